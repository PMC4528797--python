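"""Explicit decision rules.

Two rules complement the Random Forest classifiers:

* the X-Pro positive-φ tree — every X-Pro peptide with φ_i > 0 is either
  a genuine trans→cis (tc−) flip or a trans proline with broken nitrogen
  chirality ('NCh'); the two are separated by the τ angle (N_i–Cα_i–C_i)
  and the bump score of the plane O atom;
* the cis→trans candidate flag — cis-modelled peptides that are really
  trans show an inflated Cα–Cα distance and C(i−1)–N(i)–Cα(i) angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import RunConfig
from .features import FeatureVector

__all__ = ["RuleVerdict", "xpro_positive_phi_rule", "flag_cis_to_trans_candidate"]


@dataclass
class RuleVerdict:
    verdict: str  # "tc-", "NCh", "ct-candidate" or "none"
    triggers: dict = field(default_factory=dict)


def xpro_positive_phi_rule(f: FeatureVector, residue_class: str,
                           cfg: RunConfig | None = None) -> RuleVerdict:
    """Classify an X-Pro peptide with positive φ_i.

    φ_i ≤ 0 → none (tt− and tc+ prolines sit near φ = −60°).  Otherwise:
    τ > 112.5° AND bump score > 0.26 → 'NCh' (nitrogen-chirality problem,
    not a flip); anything else → tc− (trans-modelled peptide that should
    be cis).  Both inequalities are strict.
    """
    cfg = cfg or RunConfig()
    if residue_class != "X-Pro":
        raise ValueError("X-Pro positive-phi rule applies to X-Pro peptides only")
    phi = f.phi3
    triggers = {"phi3": phi, "tau3": f.tau3, "bump": f.o_bump_score}
    if phi is None or math.isnan(phi) or phi <= 0.0:
        return RuleVerdict("none", triggers)
    if f.tau3 > cfg.xpro_tau_threshold and f.o_bump_score > cfg.xpro_bump_threshold:
        return RuleVerdict("NCh", triggers)
    return RuleVerdict("tc-", triggers)


def flag_cis_to_trans_candidate(f: FeatureVector, residue_class: str,
                                cfg: RunConfig | None = None) -> RuleVerdict:
    """Advisory flag for cis-modelled peptides that may really be trans.

    Fires when the Cα–Cα distance or the C(i−1)–N(i)–Cα(i) angle exceeds
    a class-specific threshold (midpoints between the reported medians of
    correct and misassigned cis peptides).  Returns 'none' for trans
    peptides.
    """
    cfg = cfg or RunConfig()
    triggers = {"ca_ca": f.ca_ca, "ang_c2_n3_ca3": f.ang_c2_n3_ca3, "omega": f.omega}
    if abs(f.omega) > cfg.cis_max:
        return RuleVerdict("none", triggers)
    if residue_class == "X-Pro":
        ca_min, ang_min = cfg.ct_ca_min_pro, cfg.ct_angle_min_pro
    else:
        ca_min, ang_min = cfg.ct_ca_min_xnpg, cfg.ct_angle_min_xnpg
    if f.ca_ca >= ca_min or f.ang_c2_n3_ca3 >= ang_min:
        return RuleVerdict("ct-candidate", triggers)
    return RuleVerdict("none", triggers)
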