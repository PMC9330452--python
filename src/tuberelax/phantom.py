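"""Synthetic multi-echo MRI phantoms of potato tubers.

The generator emulates a 2D multi-spin-echo (MSE) acquisition of whole
tubers lying on trays: several elliptical tubers per image, each with a
thin low-signal skin, a cortex ring, a heterogeneous flesh, a brighter
central pith and (optionally) a narrow bright vascular ring at the
cortex--flesh interface.  Every tissue decays as a mixture of
exponentials,

    S(t) = PD * sum_j f_j * exp(-t / T2_j),      sum_j f_j = 1,

sampled at echo times t = TE, 2*TE, ..., n_echoes*TE, and magnitude
reconstruction turns additive complex Gaussian noise into Rician noise.

Default relaxation mixtures are the 32-DASE control values measured on
real tubers (cortex 19 %/64 ms + 81 %/268 ms, flesh 24 %/61 ms +
76 %/268 ms, pith 12 %/52 ms + 88 %/353 ms); the flesh slow-pool T2 is
set equal to the cortex value, the two being statistically
indistinguishable in the source data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RelaxationMixture",
    "TissueGeometry",
    "PhantomSpec",
    "MultiEchoImage",
    "TissueLabelMap",
    "LABEL_CODE",
    "DEFAULT_MIXTURES",
    "GeometryError",
    "default_phantom_spec",
    "render_noiseless",
    "add_rician_noise",
    "rician",
    "generate_phantom",
    "simulate_long_table",
    "mixture_signal",
]

#: Integer label code shared by the generator and the segmentation stage.
LABEL_CODE = {
    "background": 0,
    "skin": 1,
    "cortex": 2,
    "flesh": 3,
    "pith": 4,
    "vascular": 5,
}

_S3 = np.ones((3, 3), dtype=bool)


class GeometryError(ValueError):
    """Raised when a phantom specification is geometrically invalid."""


@dataclass(frozen=True)
class RelaxationMixture:
    """A discrete mixture of exponentially relaxing water pools.

    Parameters
    ----------
    components
        Sequence of ``(fraction, t2_ms)`` pairs.  Fractions must sum to
        one; the list is kept sorted by ascending T2.
    proton_density
        Signal amplitude extrapolated to zero echo time, in arbitrary
        units.
    """

    components: tuple[tuple[float, float], ...]
    proton_density: float = 100.0

    def __post_init__(self) -> None:
        comps = tuple((float(f), float(t2)) for f, t2 in self.components)
        if not comps:
            raise ValueError("mixture needs at least one component")
        if abs(sum(f for f, _ in comps) - 1.0) > 1e-9:
            raise ValueError("component fractions must sum to 1")
        if any(t2 <= 0 for _, t2 in comps):
            raise ValueError("T2 values must be strictly positive")
        object.__setattr__(self, "components", tuple(sorted(comps, key=lambda c: c[1])))
        if self.proton_density < 0:
            raise ValueError("proton density must be non-negative")

    def signal(self, times_ms: np.ndarray) -> np.ndarray:
        """Noiseless decay PD * sum_j f_j exp(-t/T2_j) at ``times_ms``."""
        t = np.asarray(times_ms, dtype=float)
        out = np.zeros_like(t)
        for f, t2 in self.components:
            out += f * np.exp(-t / t2)
        return self.proton_density * out


def mixture_signal(components: Sequence[tuple[float, float]], times_ms: np.ndarray,
                   proton_density: float = 1.0) -> np.ndarray:
    """Convenience wrapper: decay of a fraction/T2 mixture at given times."""
    return RelaxationMixture(tuple(components), proton_density).signal(times_ms)


#: 32-DASE control mixtures (fraction, T2 ms) per tissue.  The flesh
#: slow-pool T2 duplicates the cortex value; skin is a fast-relaxing,
#: low-density stand-in for the suberised periderm.
DEFAULT_MIXTURES: Mapping[str, RelaxationMixture] = {
    "cortex": RelaxationMixture(((0.19, 64.0), (0.81, 268.0)), proton_density=100.0),
    "flesh": RelaxationMixture(((0.24, 61.0), (0.76, 268.0)), proton_density=100.0),
    "pith": RelaxationMixture(((0.12, 52.0), (0.88, 353.0)), proton_density=110.0),
    "skin": RelaxationMixture(((0.5, 25.0), (0.5, 150.0)), proton_density=70.0),
}


@dataclass(frozen=True)
class TissueGeometry:
    """Geometry of one tuber in pixel units.

    Thicknesses are morphological: the skin is what one erosion with a
    ``(2*skin_thickness_px+1)``-square structuring element removes, the
    cortex the next ``cortex_thickness_px`` single-pixel erosion layers.
    ``vascular_ring`` is ``(offset_px, width_px, boost)``: a ring of
    ``width_px`` erosion layers starting ``offset_px`` layers inside the
    cortex inner boundary whose slow-pool T2 is multiplied by ``boost``.
    """

    tuber_center: tuple[float, float]
    tuber_axes: tuple[float, float]
    skin_thickness_px: int = 2
    cortex_thickness_px: int = 3
    pith_axes: tuple[float, float] = (16.0, 7.0)
    vascular_ring: Optional[tuple[int, int, float]] = None
    flesh_heterogeneity: tuple[float, float] = (0.10, 3.0)
    pith_heterogeneity: tuple[float, float] = (0.05, 3.0)

    def __post_init__(self) -> None:
        a, b = self.tuber_axes
        pa, pb = self.pith_axes
        if min(a, b) <= 0 or min(pa, pb) <= 0:
            raise GeometryError("semi-axes must be positive")
        inner = self.skin_thickness_px + self.cortex_thickness_px
        if inner >= min(a, b):
            raise GeometryError("skin+cortex thicker than tuber minor semi-axis")
        if pa >= a - inner or pb >= b - inner:
            raise GeometryError("pith not fully inside cortex inner boundary")
        for amp in (self.flesh_heterogeneity[0], self.pith_heterogeneity[0]):
            if not 0.0 <= amp <= 0.5:
                raise GeometryError("heterogeneity amplitude must be in [0, 0.5]")


@dataclass(frozen=True)
class PhantomSpec:
    """Full generative description of one synthetic acquisition."""

    image_shape: tuple[int, int] = (160, 160)
    geometries: tuple[TissueGeometry, ...] = ()
    mixtures: Mapping[str, RelaxationMixture] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURES))
    te_ms: float = 6.5
    n_echoes: int = 256
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.te_ms <= 0:
            raise ValueError("te_ms must be positive")
        if self.n_echoes < 2:
            raise ValueError("need at least 2 echoes")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for t in ("cortex", "flesh", "pith", "skin"):
            if t not in self.mixtures:
                raise ValueError(f"missing mixture for tissue {t!r}")

    @property
    def n_tubers(self) -> int:
        return len(self.geometries)

    @property
    def echo_times(self) -> np.ndarray:
        return self.te_ms * np.arange(1, self.n_echoes + 1)


@dataclass
class MultiEchoImage:
    """Stack of 2D magnitude images, one frame per echo."""

    data: np.ndarray  # (n_echoes, rows, cols), non-negative
    te_ms: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (echo, row, col)")
        if self.te_ms <= 0:
            raise ValueError("te_ms must be positive")
        if np.any(self.data < 0):
            raise ValueError("magnitude images must be non-negative")

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def echo_times(self) -> np.ndarray:
        return self.te_ms * np.arange(1, self.n_echoes + 1)


@dataclass
class TissueLabelMap:
    """Per-pixel tissue labels plus per-pixel tuber membership."""

    labels: np.ndarray      # int, values of LABEL_CODE
    tuber_ids: np.ndarray   # int, 0 = no tuber
    label_code: Mapping[str, int] = field(default_factory=lambda: dict(LABEL_CODE))
    flags: dict = field(default_factory=dict)

    def tissue_mask(self, tissue: str, tuber_id: Optional[int] = None) -> np.ndarray:
        m = self.labels == self.label_code[tissue]
        if tuber_id is not None:
            m &= self.tuber_ids == tuber_id
        return m

    @property
    def tuber_numbers(self) -> np.ndarray:
        ids = np.unique(self.tuber_ids)
        return ids[ids > 0]


def default_phantom_spec(n_tubers: int = 8, image_shape: tuple[int, int] = (160, 160),
                         noise_sigma: float = 2.0, seed: int = 0,
                         vascular: bool = False,
                         jitter: bool = True) -> PhantomSpec:
    """Default acquisition: ``n_tubers`` tubers on a 2 x 4 grid.

    Geometry mimics eight tubers aligned on two trays inside a 160 x 160
    acquisition matrix; a small seeded jitter of centres and semi-axes
    makes tubers individually distinct while keeping them well separated.
    """
    if not 1 <= n_tubers <= 8:
        raise GeometryError("default layout supports 1-8 tubers")
    rows, cols = image_shape
    grid_r, grid_c = 2, 4
    cell_r, cell_c = rows / grid_r, cols / grid_c
    # base semi-axes scale with the cell so smaller matrices stay valid
    ax_r, ax_c = 0.40 * cell_r, 0.40 * cell_c
    rng = np.random.default_rng(seed + 777)
    geoms = []
    ring = (0, 1, 1.3) if vascular else None
    for i in range(n_tubers):
        gr, gc = divmod(i, grid_c)
        cr = (gr + 0.5) * cell_r
        cc = (gc + 0.5) * cell_c
        if jitter:
            cr += rng.uniform(-1, 1)
            cc += rng.uniform(-1, 1)
            jr = rng.uniform(-1, 1)
            jc = rng.uniform(-1, 1)
        else:
            jr = jc = 0.0
        a, b = ax_r + jr, ax_c + jc
        inner = 5  # default skin (2) + cortex (3) layers
        geoms.append(TissueGeometry(
            tuber_center=(cr, cc), tuber_axes=(a, b),
            pith_axes=(0.60 * (a - inner), 0.64 * (b - inner)),
            vascular_ring=ring))
    return PhantomSpec(image_shape=image_shape, geometries=tuple(geoms),
                       noise_sigma=noise_sigma, seed=seed)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (((rr - center[0]) / axes[0]) ** 2
            + ((cc - center[1]) / axes[1]) ** 2) <= 1.0


def _heterogeneity_field(shape: tuple[int, int], amplitude: float,
                         corr_px: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field, mean 1, sd = amplitude, strictly positive."""
    if amplitude == 0:
        return np.ones(shape)
    g = ndimage.gaussian_filter(rng.standard_normal(shape), corr_px)
    g = (g - g.mean()) / g.std()
    return np.clip(1.0 + amplitude * g, 0.05, None)


def render_noiseless(spec: PhantomSpec) -> tuple[MultiEchoImage, TissueLabelMap]:
    """Render the noiseless forward model of a phantom spec.

    Returns the echo stack (signal ``PD(p) * sum_j f_j exp(-TE*k/T2_j)``
    per pixel) and the generative ground-truth label map.  Flesh proton
    density is modulated by a seeded smooth heterogeneity field of mean
    one; tissue T2 values are untouched.  Overlapping tubers are
    rejected.
    """
    shape = spec.image_shape
    labels = np.zeros(shape, dtype=np.uint8)
    tuber_ids = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)

    tissue_masks: dict[str, np.ndarray] = {
        t: np.zeros(shape, dtype=bool) for t in ("skin", "cortex", "flesh", "pith", "vascular")}
    ring_boosts: list[tuple[np.ndarray, float]] = []

    for i, g in enumerate(spec.geometries, start=1):
        tub = _ellipse_mask(shape, g.tuber_center, g.tuber_axes)
        if not tub.any():
            raise GeometryError(f"tuber {i} is empty (outside the image?)")
        if (tub & occupied).any():
            raise GeometryError(f"tuber {i} overlaps another tuber")
        occupied |= tub
        k = 2 * g.skin_thickness_px + 1
        core = ndimage.binary_erosion(tub, np.ones((k, k), dtype=bool))
        inner = core
        for _ in range(g.cortex_thickness_px):
            inner = ndimage.binary_erosion(inner, _S3)
        skin = tub & ~core
        cortex = core & ~inner
        pith = _ellipse_mask(shape, g.tuber_center, g.pith_axes) & inner
        flesh = inner & ~pith
        vasc = np.zeros(shape, dtype=bool)
        if g.vascular_ring is not None:
            off, width, boost = g.vascular_ring
            outer_band = inner
            for _ in range(off):
                outer_band = ndimage.binary_erosion(outer_band, _S3)
            band = outer_band
            for _ in range(width):
                band = ndimage.binary_erosion(band, _S3)
            vasc = (outer_band & ~band) & flesh
            flesh = flesh & ~vasc
            ring_boosts.append((vasc, boost))
        for name, m in (("skin", skin), ("cortex", cortex), ("flesh", flesh),
                        ("pith", pith), ("vascular", vasc)):
            tissue_masks[name] |= m
            labels[m] = LABEL_CODE[name]
        tuber_ids[tub] = i

    times = spec.echo_times
    data = np.zeros((spec.n_echoes,) + shape, dtype=float)
    rng = np.random.default_rng(spec.seed)
    flesh_amp, flesh_corr = (spec.geometries[0].flesh_heterogeneity
                             if spec.geometries else (0.0, 1.0))
    pith_amp, pith_corr = (spec.geometries[0].pith_heterogeneity
                           if spec.geometries else (0.0, 1.0))
    flesh_field = _heterogeneity_field(shape, flesh_amp, flesh_corr, rng)
    pith_field = _heterogeneity_field(shape, pith_amp, pith_corr, rng)

    for tissue in ("skin", "cortex", "flesh", "pith"):
        m = tissue_masks[tissue]
        if not m.any():
            continue
        decay = spec.mixtures[tissue].signal(times)  # (n_echoes,)
        pd_field = np.ones(m.sum())
        if tissue == "flesh":
            pd_field = flesh_field[m]
        elif tissue == "pith":
            pd_field = pith_field[m]
        data[:, m] = decay[:, None] * pd_field[None, :]
    # vascular ring: flesh-like mixture with the slow pool's T2 boosted
    for vasc, boost in ring_boosts:
        if not vasc.any():
            continue
        fm = spec.mixtures["flesh"]
        comps = list(fm.components)
        f_slow, t2_slow = comps[-1]
        comps[-1] = (f_slow, t2_slow * boost)
        boosted = RelaxationMixture(tuple(comps), proton_density=fm.proton_density)
        data[:, vasc] = boosted.signal(times)[:, None]

    img = MultiEchoImage(data=data, te_ms=spec.te_ms)
    return img, TissueLabelMap(labels=labels, tuber_ids=tuber_ids)


def rician(values: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of ``values`` corrupted by complex Gaussian noise.

    Each value v becomes sqrt((v+n1)^2 + n2^2) with n1, n2 ~ N(0, sigma^2);
    the background (v=0) is then Rayleigh with mean sigma*sqrt(pi/2).
    """
    v = np.asarray(values, dtype=float)
    if sigma == 0:
        return v.copy()
    n1 = rng.normal(0.0, sigma, v.shape)
    n2 = rng.normal(0.0, sigma, v.shape)
    return np.sqrt((v + n1) ** 2 + n2 ** 2)


def add_rician_noise(img: MultiEchoImage, sigma: float, seed: int,
                     gaussian: bool = False) -> MultiEchoImage:
    """Return a noisy copy of an echo stack (Rician by default).

    ``gaussian=True`` adds plain additive Gaussian noise instead
    (clipped at zero), for analytic tests only.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    if sigma == 0:
        data = img.data.copy()
    elif gaussian:
        data = np.clip(img.data + rng.normal(0.0, sigma, img.data.shape), 0.0, None)
    else:
        data = rician(img.data, sigma, rng)
    return MultiEchoImage(data=data, te_ms=img.te_ms)


def generate_phantom(spec: PhantomSpec) -> tuple[MultiEchoImage, TissueLabelMap]:
    """Render a phantom and apply its Rician noise (seeded)."""
    img, lab = render_noiseless(spec)
    noisy = add_rician_noise(img, spec.noise_sigma, seed=spec.seed + 1)
    return noisy, lab


def simulate_long_table(design: Mapping[tuple, tuple[float, float]],
                        n_per_cell: int, seed: int) -> pd.DataFrame:
    """Draw a tidy long-format measurement table from a cell design.

    ``design`` maps ``(tissue, dase, regime)`` or
    ``(tissue, dase, regime, variable)`` to ``(mean, sd)``.  Each cell
    receives ``n_per_cell`` Gaussian draws, mirroring the n = 4
    biological replication of the source experiment.
    """
    if not design:
        raise ValueError("empty design")
    if n_per_cell < 2:
        raise ValueError("n_per_cell must be >= 2")
    rng = np.random.default_rng(seed)
    records = []
    for key, (mean, sd) in design.items():
        if sd < 0:
            raise ValueError("sd must be non-negative")
        if len(key) == 3:
            tissue, dase, regime = key
            variable = "value"
        elif len(key) == 4:
            tissue, dase, regime, variable = key
        else:
            raise ValueError("design keys must be (tissue, dase, regime[, variable])")
        draws = rng.normal(mean, sd, n_per_cell) if sd > 0 else np.full(n_per_cell, mean)
        for j, v in enumerate(draws, start=1):
            records.append({
                "sample_id": f"{tissue}-{dase}-{regime}-{j}",
                "tissue": tissue, "dase": dase, "regime": regime,
                "variable": variable, "value": float(v)})
    return pd.DataFrame.from_records(records)
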