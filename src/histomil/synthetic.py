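"""Synthetic multi-center slide cohorts.

Generates desk-scale H&E-like slide images with a controllable statistical
structure: a bright background, a contiguous pink/purple tissue region,
class-dependent nuclei-like spot texture (tumor slides carry denser and
larger spots than controls), a per-dataset stain cast applied to tissue
pixels only, multiple slides per patient, and patients owning one slide of
each class.  The point is not photo-realism: it is that every downstream
stage of the pipeline (tiling, stain normalization, weakly-supervised
training, cross-dataset evaluation, batch-effect diagnosis) can be exercised
end-to-end on data whose class signal, dataset signal and class-dataset
confounding are known by construction.

The ``confounded_trio`` scenario mirrors the structure of public pancreatic
cancer collections: one source contributing almost only tumor slides, one
contributing only controls (so that in their union the class label is almost
perfectly predictable from the source), one balanced source, and a small
balanced held-out set.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ParameterError

CLASSES = ("control", "tumor")

#: Gray-white background level (mean, sd) chosen so the slide histogram is
#: cleanly bimodal for Otsu thresholding.
BACKGROUND_MEAN = 242.0
BACKGROUND_SD = 4.0

#: Eosin-pink tissue base and hematoxylin-purple spot color (RGB).
TISSUE_BASE = np.array([226.0, 158.0, 192.0])
SPOT_COLOR = np.array([88.0, 58.0, 128.0])

MANIFEST_COLUMNS = [
    "slide_id",
    "patient_id",
    "dataset_id",
    "class_label",
    "group_label",
    "path",
]


@dataclass(frozen=True)
class TextureParams:
    """Spot texture of one class: density in spots per 10^4 px^2, radius in px."""

    density: float
    radius: float


@dataclass(frozen=True)
class StainCast:
    """Per-dataset stain shift applied to tissue pixels: out = in * mult + add."""

    mult: tuple[float, float, float] = (1.0, 1.0, 1.0)
    add: tuple[int, int, int] = (0, 0, 0)

    @property
    def is_identity(self) -> bool:
        return tuple(self.mult) == (1.0, 1.0, 1.0) and tuple(self.add) == (0, 0, 0)


IDENTITY_CAST = StainCast()

#: Default class textures: tumor doubles spot density and grows the radius
#: by 1.5x relative to control -- the simplest texture contrast a small CNN
#: can learn quickly while remaining invisible to naive color statistics.
DEFAULT_TEXTURE = {
    "control": TextureParams(density=6.0, radius=3.0),
    "tumor": TextureParams(density=12.0, radius=4.5),
}


@dataclass(frozen=True)
class DatasetSpec:
    dataset_id: str
    n_patients_control: int
    n_patients_tumor: int


@dataclass(frozen=True)
class CohortSpec:
    """Full description of one synthetic cohort.

    ``dual_class_patient_rate`` is the fraction of distinct patients that own
    one slide of each class (only meaningful in datasets providing both
    classes).  ``tumor_purity`` is the fraction of tissue inside a tumor
    slide that carries tumor texture; the remainder keeps control texture,
    emulating the normal tissue found inside real tumor resections.
    """

    datasets: tuple[DatasetSpec, ...]
    slide_size: tuple[int, int] = (1024, 1024)
    tissue_fraction: float = 0.85
    texture_params: dict = field(default_factory=lambda: dict(DEFAULT_TEXTURE))
    stain_cast: dict = field(default_factory=dict)
    slides_per_patient: int = 1
    dual_class_patient_rate: float = 0.0
    tumor_purity: float = 0.8
    group_labels: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ParameterError("CohortSpec requires at least one dataset")
        for ds in self.datasets:
            if ds.n_patients_control < 0 or ds.n_patients_tumor < 0:
                raise ParameterError(f"negative patient count in {ds.dataset_id}")
        if not (0.0 < self.tissue_fraction <= 1.0):
            raise ParameterError("tissue_fraction must be in (0, 1]")
        if not (0.0 <= self.dual_class_patient_rate <= 1.0):
            raise ParameterError("dual_class_patient_rate must be in [0, 1]")
        if self.slides_per_patient < 1:
            raise ParameterError("slides_per_patient must be >= 1")
        max_radius = max(p.radius for p in self.texture_params.values())
        if max_radius >= min(self.slide_size) / 4:
            raise ParameterError("spot radius must be < min(slide_size)/4")

    def cast_for(self, dataset_id: str) -> StainCast:
        return self.stain_cast.get(dataset_id, IDENTITY_CAST)


@dataclass
class SlideRecord:
    """One slide image plus its identity; the unit of preprocessing."""

    slide_id: str
    patient_id: str
    dataset_id: str
    class_label: str
    image: np.ndarray
    group_label: str | None = None


def _derive_rng(seed: int, *tokens: str) -> np.random.Generator:
    """Deterministic per-object RNG: stable across runs and call order."""
    crc = zlib.crc32("/".join(tokens).encode())
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, crc]))


def _tissue_mask(shape: tuple[int, int], fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Contiguous superellipse-shaped tissue region covering ~``fraction`` of the slide."""
    h, w = shape
    if fraction >= 0.999:
        return np.ones(shape, dtype=bool)
    # |x/a|^4 + |y/b|^4 <= 1 has area ~3.708*a*b; solve for the semi-axes.
    target = fraction * h * w
    aspect = rng.uniform(0.85, 1.18)
    a = np.sqrt(target / 3.708 / aspect)
    b = a * aspect
    a = min(a, 0.499 * w)
    b = min(b, 0.499 * h)
    cy = h / 2 + rng.uniform(-0.02, 0.02) * h
    cx = w / 2 + rng.uniform(-0.02, 0.02) * w
    yy = (np.arange(h)[:, None] - cy) / b
    xx = (np.arange(w)[None, :] - cx) / a
    return (yy**4 + xx**4) <= 1.0


def _draw_spots(
    mask_region: np.ndarray,
    params: TextureParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean mask of dark elliptical nuclei-like spots inside ``mask_region``."""
    h, w = mask_region.shape
    area = int(mask_region.sum())
    spot_mask = np.zeros((h, w), dtype=bool)
    n_spots = int(round(params.density * area / 1.0e4))
    if n_spots == 0 or area == 0:
        return spot_mask
    ys, xs = np.nonzero(mask_region)
    centers = rng.integers(0, len(ys), size=n_spots)
    r_major = params.radius * rng.uniform(0.75, 1.25, size=n_spots)
    r_minor = params.radius * rng.uniform(0.6, 1.0, size=n_spots)
    angles = rng.uniform(0, np.pi, size=n_spots)
    from skimage.draw import ellipse as _ellipse

    for i, ci in enumerate(centers):
        rr, cc = _ellipse(
            ys[ci], xs[ci], r_major[i], r_minor[i],
            shape=(h, w), rotation=angles[i],
        )
        spot_mask[rr, cc] = True
    return spot_mask & mask_region


def render_slide_image(
    class_label: str,
    spec: CohortSpec,
    cast: StainCast,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one slide; returns (image, tissue_mask, spot_mask).

    Exposed separately from :func:`generate_slide` so that tests can reason
    about the generated masks (spot counts, tissue coverage) directly.
    """
    if class_label not in CLASSES:
        raise ParameterError(f"unknown class label {class_label!r}")
    h, w = spec.slide_size

    gray = BACKGROUND_MEAN + BACKGROUND_SD * rng.standard_normal((h, w), dtype=np.float32)
    img = gray[:, :, None] + rng.standard_normal((h, w, 3), dtype=np.float32)

    tissue = _tissue_mask((h, w), spec.tissue_fraction, rng)

    # Pink base with a smooth low-frequency mottle plus fine grain.
    # The mottle is rendered at quarter resolution (it only carries
    # wavelengths of ~100 px) and upsampled.
    hq, wq = max(h // 4, 1), max(w // 4, 1)
    mottle_q = gaussian_filter(rng.standard_normal((hq, wq), dtype=np.float32), sigma=10.0)
    mottle = np.kron(mottle_q, np.ones((4, 4), dtype=np.float32))[:h, :w]
    if mottle.shape != (h, w):  # tiny slides
        pad_h, pad_w = h - mottle.shape[0], w - mottle.shape[1]
        mottle = np.pad(mottle, ((0, pad_h), (0, pad_w)), mode="edge")
    mottle = mottle / (np.abs(mottle).max() + 1e-12) * 10.0
    base = TISSUE_BASE[None, None, :].astype(np.float32) + mottle[:, :, None]
    base = base + 4.0 * rng.standard_normal((h, w, 3), dtype=np.float32)
    img[tissue] = base[tissue]

    # Class texture.  Tumor slides keep a contiguous band of control texture
    # (1 - tumor_purity of the tissue) emulating intratumoral normal tissue.
    if class_label == "tumor" and spec.tumor_purity < 1.0:
        cols = tissue.sum(axis=0)
        cum = np.cumsum(cols) / max(cols.sum(), 1)
        left_is_tumor = bool(rng.integers(0, 2))
        col_idx = np.arange(w)[None, :]
        if left_is_tumor:
            split = int(np.searchsorted(cum, spec.tumor_purity))
            tumor_region = tissue & (col_idx < split)
        else:
            split = int(np.searchsorted(cum, 1.0 - spec.tumor_purity))
            tumor_region = tissue & (col_idx >= split)
        control_region = tissue & ~tumor_region
        spot_mask = _draw_spots(tumor_region, spec.texture_params["tumor"], rng)
        spot_mask |= _draw_spots(control_region, spec.texture_params["control"], rng)
    else:
        spot_mask = _draw_spots(tissue, spec.texture_params[class_label], rng)

    n_spot_px = int(spot_mask.sum())
    spot_color = SPOT_COLOR[None, :].astype(np.float32) + 8.0 * rng.standard_normal(
        (n_spot_px, 3), dtype=np.float32
    )
    img[spot_mask] = spot_color

    # Dataset stain cast on tissue pixels only (spots are tissue).
    if not cast.is_identity:
        img[tissue] = img[tissue] * np.asarray(cast.mult, dtype=np.float32)[None, :] + np.asarray(
            cast.add, dtype=np.float32
        )[None, :]

    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, tissue, spot_mask


def generate_slide(
    patient_id: str,
    class_label: str,
    dataset_id: str,
    spec: CohortSpec,
    rng_state: np.random.Generator,
    slide_id: str | None = None,
    group_label: str | None = None,
) -> SlideRecord:
    """Generate a single synthetic slide, deterministic given ``rng_state``."""
    if not any(d.dataset_id == dataset_id for d in spec.datasets):
        raise ParameterError(f"dataset {dataset_id!r} not in spec")
    cast = spec.cast_for(dataset_id)
    img, _, _ = render_slide_image(class_label, spec, cast, rng_state)
    if slide_id is None:
        slide_id = f"{patient_id}_{class_label}_0"
    return SlideRecord(
        slide_id=slide_id,
        patient_id=patient_id,
        dataset_id=dataset_id,
        class_label=class_label,
        image=img,
        group_label=group_label,
    )


def _patient_plan(spec: CohortSpec, ds: DatasetSpec) -> list[tuple[str, tuple[str, ...]]]:
    """Plan (patient_id, classes) for one dataset, honoring the dual-class rate.

    ``n_dual = round(rate * P / (1 + rate))`` where ``P`` is the number of
    per-class patient slots, so that dual patients form ``rate`` of the
    resulting distinct patients.  A dual patient fills one control and one
    tumor slot and owns exactly one slide of each class.
    """
    n_c, n_t = ds.n_patients_control, ds.n_patients_tumor
    rate = spec.dual_class_patient_rate
    n_dual = 0
    if rate > 0.0:
        if min(n_c, n_t) == 0:
            raise ParameterError(
                f"dual-class patients requested but dataset {ds.dataset_id} "
                "provides only one class"
            )
        n_dual = min(int(round(rate * (n_c + n_t) / (1.0 + rate))), n_c, n_t)
    plan: list[tuple[str, tuple[str, ...]]] = []
    idx = 0
    for _ in range(n_dual):
        plan.append((f"{ds.dataset_id}-P{idx:03d}", ("control", "tumor")))
        idx += 1
    for _ in range(n_c - n_dual):
        plan.append((f"{ds.dataset_id}-P{idx:03d}", ("control",)))
        idx += 1
    for _ in range(n_t - n_dual):
        plan.append((f"{ds.dataset_id}-P{idx:03d}", ("tumor",)))
        idx += 1
    return plan


def generate_cohort(spec: CohortSpec) -> tuple[list[SlideRecord], pd.DataFrame]:
    """Generate every slide of a cohort plus its manifest.

    Patient counts per (dataset, class) match the spec exactly; the manifest
    has one row per slide and is serializable as tab-delimited text.
    """
    slides: list[SlideRecord] = []
    rows = []
    for ds in spec.datasets:
        plan = _patient_plan(spec, ds)
        groups = spec.group_labels.get(ds.dataset_id)
        for p_idx, (pid, classes) in enumerate(plan):
            group = groups[p_idx % len(groups)] if groups else None
            dual = len(classes) > 1
            for cls in classes:
                # Dual patients own exactly one slide per class.
                n_slides = 1 if dual else spec.slides_per_patient
                for j in range(n_slides):
                    sid = f"{pid}_{cls}_{j}"
                    rng = _derive_rng(spec.seed, sid)
                    rec = generate_slide(
                        pid, cls, ds.dataset_id, spec, rng,
                        slide_id=sid, group_label=group,
                    )
                    slides.append(rec)
                    rows.append(
                        dict(
                            slide_id=sid,
                            patient_id=pid,
                            dataset_id=ds.dataset_id,
                            class_label=cls,
                            group_label=group if group is not None else "",
                            path="",
                        )
                    )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return slides, manifest


# --- the confounded multi-center scenario -------------------------------

#: Opposing stain casts for the tumor-heavy (A) and control-only (B)
#: sources, a mild warm cast for the balanced source (C) and a distinct
#: cool cast for the held-out set (T).  A/B magnitudes are chosen well above
#: the class-induced mean-color shift so that, in A+B, source (and hence
#: class) is readable from color alone.
SCENARIO_CASTS = {
    "A": StainCast(mult=(1.28, 0.74, 0.86), add=(22, -18, -10)),
    "B": StainCast(mult=(0.74, 1.22, 1.30), add=(-22, 18, 14)),
    "C": StainCast(mult=(1.02, 0.98, 1.00), add=(2, 0, 2)),
    "T": StainCast(mult=(0.97, 1.03, 0.99), add=(-4, 4, 0)),
}

SCENARIO_COUNTRIES = (
    "US", "Poland", "China", "Canada", "Russia", "Germany",
    "Spain", "France", "Japan", "Brazil", "India", "Other",
)


def make_multicenter_scenario(
    preset_name: str = "confounded_trio",
    scale: int = 1,
    seed: int = 0,
    identity_casts: bool = False,
    slide_size: tuple[int, int] = (1024, 1024),
) -> dict[str, tuple[list[SlideRecord], pd.DataFrame, CohortSpec]]:
    """Build the confounded three-source scenario plus a held-out cohort.

    Returns a dict with cohorts ``A`` (tumor-heavy: 20*scale tumor patients
    of which 2*scale also contribute a control slide), ``B`` (20*scale
    control-only patients), ``C`` (balanced 12+12*scale, with per-patient
    country labels for grouped cross-validation) and ``T`` (balanced
    5+5*scale held-out).  ``identity_casts=True`` disables every stain cast,
    switching off the color route to the class label while leaving the
    texture signal untouched.
    """
    if preset_name != "confounded_trio":
        raise ParameterError(f"unknown preset {preset_name!r}")
    if scale < 1:
        raise ParameterError("scale must be >= 1")

    def cast(name: str) -> dict:
        return {} if identity_casts else {name: SCENARIO_CASTS[name]}

    def sub_seed(i: int) -> int:
        return (seed * 1_000_003 + i) % (2**31)

    specs = {
        "A": CohortSpec(
            datasets=(DatasetSpec("A", 2 * scale, 20 * scale),),
            stain_cast=cast("A"),
            # 2*scale dual patients out of 20*scale distinct patients.
            dual_class_patient_rate=0.1,
            slide_size=slide_size,
            seed=sub_seed(1),
        ),
        "B": CohortSpec(
            datasets=(DatasetSpec("B", 20 * scale, 0),),
            stain_cast=cast("B"),
            slide_size=slide_size,
            seed=sub_seed(2),
        ),
        "C": CohortSpec(
            datasets=(DatasetSpec("C", 12 * scale, 12 * scale),),
            stain_cast=cast("C"),
            group_labels={"C": list(SCENARIO_COUNTRIES)},
            slide_size=slide_size,
            seed=sub_seed(3),
        ),
        "T": CohortSpec(
            datasets=(DatasetSpec("T", 5 * scale, 5 * scale),),
            stain_cast=cast("T"),
            slide_size=slide_size,
            seed=sub_seed(4),
        ),
    }
    out = {}
    for name, cspec in specs.items():
        slides, manifest = generate_cohort(cspec)
        out[name] = (slides, manifest, cspec)
    return out


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"manifest missing columns: {sorted(missing)}")
    return df
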