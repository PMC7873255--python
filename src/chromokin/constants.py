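"""Shared physical constants and default analysis parameters.

Units are micrometres (um), seconds (s) and base pairs (bp) throughout the
package; anything else is stated in the name.
"""

from scipy.constants import Avogadro as AVOGADRO  # 1/mol

# --- fast-tracking (67 Hz) acquisition and Spot-On-style fit defaults ---
FRAME_INTERVAL_FAST_S = 0.015     # 15 ms exposure, continuous acquisition
LOC_ERROR_UM = 0.04               # localization error used in kinetic fits
DZ_UM = 0.7                       # axial detection-slab depth (HILO)
JUMP_BIN_WIDTH_UM = 0.01
JUMP_MAX_UM = 5.05
N_LAGS = 8
MAX_JUMPS_PER_TRACK = 4
FIT_RESTARTS = 3
D_BOUNDS = (1e-4, 25.0)           # um^2/s, optimizer box for diffusion coeffs

# --- linking radii per imaging regime ---
LINK_RADIUS_FAST_UM = 0.768       # 67 Hz
LINK_RADIUS_2HZ_UM = 0.192        # 2 Hz binding-time movies
LINK_RADIUS_SLOW_UM = 0.672       # 0.03 Hz binding-time movies
LINK_MEMORY_FRAMES = 1            # single-frame blinking tolerance
LOC_PRECISION_UM = 0.025          # nominal localization precision

# --- slow-tracking dwell-time regime ---
FRAME_INTERVAL_2HZ_S = 0.5
T_BLEACH_TYPICAL_S = 50.0         # H2B control survival, typical value

# --- 3D nuclear-body (Polycomb body) analysis ---
ROLLING_BALL_RADIUS_PX = 4
FOCUS_VOLUME_MIN_UM3 = 0.029
FOCUS_VOLUME_MAX_UM3 = 1.5
Z_STEP_UM = 0.15

# --- genome / histone-modification budget (mouse ES cells, 2n) ---
GENOME_SIZE_2N_BP = 5_461_710_950
NUCLEOSOME_SPACING_BP = 186.1
H2A_PER_NUCLEOSOME = 2
FRAC_H2A_UB = 0.10                # fraction of H2A carrying K119ub1
UB_HALF_LIFE_S = 5400.0           # 90 min turnover half-life
MAPPABLE_FRACTION = 0.88          # uniquely mappable genome fraction
PLOIDY = 2
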