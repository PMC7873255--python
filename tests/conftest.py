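import numpy as np
import pandas as pd
import pytest

from chromokin.tracks import TrackSet


@pytest.fixture
def toy_tracks() -> TrackSet:
    """Three short tracks with distinct geometries (15 ms frames)."""
    rows = []
    # track 0: stationary
    for f in range(6):
        rows.append((0, f, 0.3, 0.4))
    # track 1: constant step of 0.2 um in x
    for f in range(6):
        rows.append((1, f, 1.0 + 0.2 * f, 2.0))
    # track 2: two points, displacement 0.33 um
    rows.append((2, 0, 5.0, 5.0))
    rows.append((2, 1, 5.33, 5.0))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])
    df["t_s"] = df["frame"] * 0.015
    return TrackSet(df[["track_id", "frame", "t_s", "x_um", "y_um"]], 0.015)


def gaussian_spot(shape, center, amplitude, sd, offset=0.0):
    """Noiseless elliptical Gaussian test image (row, col center)."""
    yy, xx = np.indices(shape, dtype=float)
    r0, c0 = center
    sr, sc = (sd, sd) if np.isscalar(sd) else sd
    return offset + amplitude * np.exp(
        -((yy - r0) ** 2 / (2 * sr**2) + (xx - c0) ** 2 / (2 * sc**2))
    )
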