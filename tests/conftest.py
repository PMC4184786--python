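import numpy as np
import pytest

from erclust import synth


@pytest.fixture(scope="session")
def paper_scale_cfg():
    """Live-imaging sampling scale: 0.5 s interval, 300 frames, subdiffusion."""
    return synth.TrackSimConfig(D=0.0045, alpha=0.74, n_frames=300, frame_interval=0.5)


@pytest.fixture(scope="session")
def clean_pair_cfg():
    """Noise-free rendered cluster pair with a 16% green shell."""
    return synth.ImageSimConfig(
        core_diameter=1.0,
        shell_growth_fraction=0.16,
        noise_model="none",
        image_shape=(64, 64),
        seed=0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def brute_force_msd(x, y, frame_interval, k_max):
    """Oracle: time-averaged MSD by an explicit double loop over all pairs."""
    n = len(x)
    lags, values, pairs = [], [], []
    for k in range(1, k_max + 1):
        acc = 0.0
        cnt = 0
        for i in range(n - k):
            acc += (x[i + k] - x[i]) ** 2 + (y[i + k] - y[i]) ** 2
            cnt += 1
        lags.append(k * frame_interval)
        values.append(acc / cnt)
        pairs.append(cnt)
    return np.array(lags), np.array(values), np.array(pairs)


def brute_force_fwhm(offsets, intensities, background, upsample=100):
    """Oracle: upsample the profile by linear interpolation and scan for the
    half-max crossings nearest the peak."""
    fine_x = np.linspace(offsets[0], offsets[-1], (len(offsets) - 1) * upsample + 1)
    fine_i = np.interp(fine_x, offsets, intensities)
    peak_idx = int(np.argmax(fine_i))
    half = background + 0.5 * (fine_i[peak_idx] - background)
    left = peak_idx
    while left > 0 and fine_i[left] >= half:
        left -= 1
    right = peak_idx
    while right < len(fine_i) - 1 and fine_i[right] >= half:
        right += 1
    if fine_i[left] >= half or fine_i[right] >= half:
        raise ValueError("unbounded peak")
    return fine_x[right] - fine_x[left]
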