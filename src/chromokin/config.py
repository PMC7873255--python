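"""Run configuration: every tunable parameter with its default value.

Defaults are the values used throughout the analysis (bin width 0.01 um,
8 lags, 4 jumps per track, 5.05 um maximum jump, sigma 0.04 um, dZ
0.7 um, linking radii 0.768/0.192/0.672 um, memory 1, rolling ball 4 px,
focus volume window [0.029, 1.5] um^3, 2n genome 5,461,710,950 bp,
nucleosome spacing 186.1 bp, 10% H2A ubiquitylation, 5400 s half-life,
0.88 mappable fraction).  A YAML file overrides any subset; unknown keys
are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from . import constants as C


@dataclass
class RunConfig:
    seed: int = 0
    # jump-length / kinetic fit
    frame_interval_s: float = C.FRAME_INTERVAL_FAST_S
    bin_width_um: float = C.JUMP_BIN_WIDTH_UM
    max_jump_um: float = C.JUMP_MAX_UM
    n_lags: int = C.N_LAGS
    max_jumps_per_track: int = C.MAX_JUMPS_PER_TRACK
    loc_error_um: float = C.LOC_ERROR_UM
    dz_um: float = C.DZ_UM
    fit_restarts: int = C.FIT_RESTARTS
    n_states: int = 3
    # localization / linking
    link_radius_um: float = C.LINK_RADIUS_FAST_UM
    link_radius_2hz_um: float = C.LINK_RADIUS_2HZ_UM
    link_radius_slow_um: float = C.LINK_RADIUS_SLOW_UM
    link_memory: int = C.LINK_MEMORY_FRAMES
    pixel_size_um: float = 0.1
    intensity_threshold: float = 0.0
    # dwell analysis
    t_bleach_s: float = C.T_BLEACH_TYPICAL_S
    min_dwell_track_length: int = 2
    # foci
    rolling_ball_radius_px: int = C.ROLLING_BALL_RADIUS_PX
    focus_volume_min_um3: float = C.FOCUS_VOLUME_MIN_UM3
    focus_volume_max_um3: float = C.FOCUS_VOLUME_MAX_UM3
    voxel_z_um: float = C.Z_STEP_UM
    voxel_y_um: float = 0.1
    voxel_x_um: float = 0.1
    # genome budget
    genome_size_bp: float = C.GENOME_SIZE_2N_BP
    nucleosome_spacing_bp: float = C.NUCLEOSOME_SPACING_BP
    frac_ub: float = C.FRAC_H2A_UB
    half_life_s: float = C.UB_HALF_LIFE_S
    mappable_fraction: float = C.MAPPABLE_FRACTION
    ploidy: int = C.PLOIDY

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
        return cls(**raw)
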