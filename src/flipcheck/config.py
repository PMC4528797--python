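"""Run configuration: every tunable threshold in one place.

Defaults follow the published method where it states a value (resolution
3.5 Å, chain length 25, τ/bump thresholds of the X-Pro rule, WH score
thresholds) and documented surrogates elsewhere (cis/trans ω cutoffs,
carbonyl-flip separatrix, bump vdW table, cis→trans heuristic midpoints).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml


@dataclass
class RunConfig:
    # entry selection
    max_resolution: float = 3.5        # Å, "3.5 or better"
    min_chain_length: int = 25         # amino acids in at least one chain
    allow_unknown_method: bool = True  # headerless fixture files
    # tetrapeptide selection
    break_distance: float = 2.5        # Å, C(i)–N(i+1) beyond this = chain break
    o_contact_distance: float = 2.5    # Å, foreign-atom clearance of central O
    # conformation assignment
    cis_max: float = 30.0              # |ω| ≤ cis_max → cis
    trans_min: float = 150.0           # |ω| ≥ trans_min → trans
    co_flip_angle: float = 90.0        # (C=O, C=O) angle above this = carbonyl flip
    # bump score
    bump_cutoff: float = 4.0           # Å neighbour search radius
    vdw_radii: dict = field(
        default_factory=lambda: {"O": 1.52, "N": 1.55, "C": 1.70, "S": 1.80}
    )
    # X-Pro positive-φ decision rule
    xpro_tau_threshold: float = 112.5  # degrees
    xpro_bump_threshold: float = 0.26  # bump units (requires local recalibration)
    # WH penalty score thresholds
    wh_threshold_original: float = 143.10
    wh_threshold_redetermined: float = 82.256
    # cis→trans candidate heuristics (midpoints between reported medians)
    ct_ca_min_xnpg: float = 3.2        # Å
    ct_ca_min_pro: float = 3.3         # Å
    ct_angle_min_xnpg: float = 131.0   # degrees, C(i−1)–N(i)–Cα(i)
    ct_angle_min_pro: float = 140.0    # degrees
    # secondary structure / helix alignment
    helix_window: int = 8              # residues scanned for a nearby helix
    # classifier settings
    n_trees: int = 500
    cv_folds: int = 5
    cv_repeats: int = 2
    resolution_max_ttplus: float = 2.2   # Å, tt+ training window
    resolution_max_gly_ttplus: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        bad = sorted(set(data) - known)
        if bad:
            raise ValueError(f"unknown config keys: {', '.join(bad)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
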