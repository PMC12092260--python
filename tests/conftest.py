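import numpy as np
import pytest

from fpscan.phantom import PressureVolume


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


def cone_limited_phantom(
    nx: int, nz: int, dx_um: float, dz_um: float, seed: int = 3,
    cone_margin: float = 1.0, z_span=(None, None),
) -> PressureVolume:
    """Smooth band-limited random phantom with spectral support inside
    the planar-detection acceptance cone (|k_par| < |kz| / margin)."""
    rng = np.random.default_rng(seed)
    W = np.fft.fftn(rng.standard_normal((nx, nx, nz)))
    kx = 2 * np.pi * np.fft.fftfreq(nx, dx_um)
    kz = 2 * np.pi * np.fft.fftfreq(nz, dz_um)
    KX, KY, KZ = np.meshgrid(kx, kx, kz, indexing="ij")
    kpar = np.hypot(KX, KY)
    kmag = np.sqrt(kpar**2 + KZ**2)
    W *= (np.abs(KZ) > cone_margin * kpar) * np.exp(
        -((kmag - 0.004) / 0.0015) ** 2
    )
    p0 = np.real(np.fft.ifftn(W))
    lo = z_span[0] if z_span[0] is not None else nz // 6
    hi = z_span[1] if z_span[1] is not None else nz - nz // 6
    win = np.zeros(nz)
    win[lo:hi] = np.hanning(hi - lo)
    return PressureVolume(p0 * win[None, None, :], dx_um, dx_um, dz_um)


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two arrays."""
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


# -- shared heavy study results (computed once per session) ------------------

@pytest.fixture(scope="session")
def psf_result():
    from fpscan.studies import psf_study

    return psf_study()


@pytest.fixture(scope="session")
def autofocus_1547():
    from fpscan.studies import autofocus_study

    return autofocus_study(1547.0)


@pytest.fixture(scope="session")
def autofocus_1650():
    from fpscan.studies import autofocus_study

    return autofocus_study(1650.0)


@pytest.fixture(scope="session")
def pulsatile_result():
    from fpscan.studies import pulsatile_study

    return pulsatile_study(epsilon=0.05)


@pytest.fixture(scope="session")
def cs_study_result():
    from fpscan.studies import subsampling_cnr_study

    return subsampling_cnr_study(seed=11, keep_volumes=True)


@pytest.fixture(scope="session")
def dynamics_result():
    from fpscan.studies import dynamics_study

    return dynamics_study()
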