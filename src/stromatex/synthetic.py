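"""Seeded synthetic fixtures: fiber tiles, TMA layouts and per-core cell tables.

No imaging or per-cell data is publicly deposited for the cohort this
pipeline targets, so every stage is exercised on synthetic inputs with
known ground truth.  Three generators cover the three data modalities:

* :func:`generate_fiber_tile` renders extracellular-matrix fiber textures
  as constant-width random-walk strokes with controlled width, curvature
  and orientation alignment -- the three properties that distinguish the
  COL11A1+ "thin linear" phenotype from the COL11A1- "thick curly"
  phenotype -- and converts accumulated blue/red stain densities to RGB
  through the same Beer-Lambert forward model the deconvolution inverts,
  so density ground truth is exact.
* :func:`generate_tma_layout` builds a tissue-microarray manifest
  (default 42 patients x 3 matched samples x 3 cores = 378 cores on two
  slides).
* :func:`generate_cell_table` emulates the per-cell CSV export of a cell
  detection tool, with ground-truth cell-type composition, marker-positive
  CAF fractions and per-compartment CD8+ fractions.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stains import MASSON_TRICHROME, DensityChannels, StainMatrix, density_to_rgb

__all__ = [
    "FiberPhenotype",
    "FiberTileSpec",
    "FiberTile",
    "LabeledTileset",
    "TmaLayout",
    "CoreTruth",
    "CohortScenario",
    "SyntheticCohort",
    "generate_fiber_tile",
    "generate_labeled_tileset",
    "generate_tma_layout",
    "generate_cell_table",
    "generate_cohort",
    "derive_seed",
]

SAMPLE_LABELS = ("PRIMARY", "METASTASIS", "RECURRENCE")

CELL_TABLE_COLUMNS = [
    "cell_id", "x", "y", "cell_type", "compartment",
    "dab_col11a1", "dab_asma", "dab_pdpn", "cd8_positive",
]


def derive_seed(master_seed: int, *key: int) -> int:
    """Derive a child seed from a master seed and an index key.

    Uses numpy's SeedSequence keyed by ``(master_seed, *key)``: a fixed,
    documented counter scheme so any subset of generated objects is
    reproducible from the master seed alone.
    """
    return int(np.random.SeedSequence((master_seed, *key)).generate_state(1)[0] % 2**31)


class FiberPhenotype(enum.Enum):
    THIN_LINEAR = "THIN_LINEAR"    # COL11A1+-like ECM
    THICK_CURLY = "THICK_CURLY"    # COL11A1--like ECM


@dataclass(frozen=True)
class FiberTileSpec:
    """Parameters of one synthetic fiber tile.

    ``curvature`` is the standard deviation (radians) of per-step heading
    increments of the random walk; ``orientation_kappa`` is the von Mises
    concentration of initial headings (0 = isotropic); ``stain_mix`` gives
    the (blue, red) OD density contributed by a fiber pixel.
    """

    phenotype: FiberPhenotype
    height: int = 200
    width: int = 200
    n_fibers: int = 20
    width_range: tuple[float, float] = (2.0, 4.0)
    curvature: float = 0.1
    orientation_kappa: float = 0.0
    stain_mix: tuple[float, float] = (0.6, 0.2)
    background_density: float = 0.05
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("tile dimensions must be positive")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        lo, hi = self.width_range
        if lo <= 0 or hi < lo:
            raise ValueError("width_range must satisfy 0 < lo <= hi")
        if any(w < 0 for w in self.stain_mix):
            raise ValueError("stain_mix weights must be >= 0")
        if self.background_density < 0 or self.noise_sd < 0:
            raise ValueError("background_density and noise_sd must be >= 0")

    @classmethod
    def thin_linear(cls, seed: int = 0, **overrides) -> "FiberTileSpec":
        """Default COL11A1+-like phenotype: thin, straight, aligned fibers
        staining with a blue/red mixture."""
        base = cls(
            phenotype=FiberPhenotype.THIN_LINEAR,
            n_fibers=40,
            width_range=(1.0, 3.0),
            curvature=0.02,
            orientation_kappa=4.0,
            stain_mix=(0.55, 0.35),
            seed=seed,
        )
        return replace(base, **overrides) if overrides else base

    @classmethod
    def thick_curly(cls, seed: int = 0, **overrides) -> "FiberTileSpec":
        """Default COL11A1--like phenotype: thick, curly, isotropic fibers
        staining primarily with aniline blue."""
        base = cls(
            phenotype=FiberPhenotype.THICK_CURLY,
            n_fibers=12,
            width_range=(6.0, 12.0),
            curvature=0.3,
            orientation_kappa=0.0,
            stain_mix=(0.80, 0.08),
            seed=seed,
        )
        return replace(base, **overrides) if overrides else base

    @classmethod
    def for_phenotype(cls, phenotype: FiberPhenotype, seed: int = 0, **overrides) -> "FiberTileSpec":
        if phenotype is FiberPhenotype.THIN_LINEAR:
            return cls.thin_linear(seed=seed, **overrides)
        return cls.thick_curly(seed=seed, **overrides)


@dataclass
class FiberTile:
    """A rendered tile: RGB image plus noiseless density ground truth."""

    rgb: np.ndarray                 # (H, W, 3) uint8
    truth: DensityChannels          # pre-noise blue/red density maps
    fiber_mask: np.ndarray          # (H, W) bool, union of fiber strokes
    spec: FiberTileSpec


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = max(int(np.ceil(radius)), 0)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= max(radius, 0.5) ** 2
    return dy[keep], dx[keep]


def generate_fiber_tile(spec: FiberTileSpec, matrix: StainMatrix = MASSON_TRICHROME) -> FiberTile:
    """Render one tile from its spec (deterministic in ``spec.seed``).

    Each fiber is a random walk of unit steps: initial heading drawn from
    a von Mises distribution with concentration ``orientation_kappa``,
    per-step heading increments Normal(0, curvature), stroke width drawn
    uniformly from ``width_range`` and stamped as a disk at every step.
    Per-fiber masks contribute ``stain_mix`` densities once (no build-up
    along a self-overlapping path); overlapping fibers add.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    blue = np.full((h, w), float(spec.background_density))
    red = np.full((h, w), float(spec.background_density))
    fiber_mask = np.zeros((h, w), dtype=bool)
    blue_w, red_w = spec.stain_mix
    n_steps = int(1.5 * max(h, w))

    for _ in range(spec.n_fibers):
        y = rng.uniform(0, h)
        x = rng.uniform(0, w)
        theta = rng.vonmises(0.0, spec.orientation_kappa) if spec.orientation_kappa > 0 else rng.uniform(-np.pi, np.pi)
        width_px = rng.uniform(*spec.width_range)
        steps = rng.normal(0.0, spec.curvature, size=n_steps)
        thetas = theta + np.cumsum(steps)
        ys = y + np.concatenate([[0.0], np.cumsum(np.sin(thetas))])
        xs = x + np.concatenate([[0.0], np.cumsum(np.cos(thetas))])

        dy, dx = _disk_offsets(width_px / 2.0)
        py = (np.floor(ys + 0.5).astype(int)[:, None] + dy[None, :]).ravel()
        px = (np.floor(xs + 0.5).astype(int)[:, None] + dx[None, :]).ravel()
        ok = (py >= 0) & (py < h) & (px >= 0) & (px < w)
        mask_f = np.zeros((h, w), dtype=bool)
        mask_f[py[ok], px[ok]] = True

        blue += blue_w * mask_f
        red += red_w * mask_f
        fiber_mask |= mask_f

    truth = DensityChannels(blue=blue.copy(), red=red.copy(), hematoxylin=np.zeros((h, w)), stain_matrix=matrix)
    if spec.noise_sd > 0:
        blue = np.clip(blue + rng.normal(0.0, spec.noise_sd, size=(h, w)), 0.0, None)
        red = np.clip(red + rng.normal(0.0, spec.noise_sd, size=(h, w)), 0.0, None)
    noisy = DensityChannels(blue=blue, red=red, hematoxylin=np.zeros((h, w)), stain_matrix=matrix)
    rgb = density_to_rgb(noisy, matrix=matrix)
    return FiberTile(rgb=rgb, truth=truth, fiber_mask=fiber_mask, spec=spec)


@dataclass
class LabeledTileset:
    """Tiles with binary COL11A1-positivity labels (True = positive)."""

    tiles: list[FiberTile]
    labels: np.ndarray  # bool per tile

    def __len__(self) -> int:
        return len(self.tiles)


def generate_labeled_tileset(
    n_pos: int,
    n_neg: int,
    seed: int = 0,
    pos_overrides: dict | None = None,
    neg_overrides: dict | None = None,
    matrix: StainMatrix = MASSON_TRICHROME,
) -> LabeledTileset:
    """Generate ``n_pos`` thin-linear (positive) and ``n_neg`` thick-curly
    (negative) tiles, each with a distinct seed derived from ``seed``."""
    if n_pos < 0 or n_neg < 0:
        raise ValueError("tile counts must be >= 0")
    tiles: list[FiberTile] = []
    labels = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    for i in range(n_pos + n_neg):
        positive = bool(labels[i])
        spec = FiberTileSpec.for_phenotype(
            FiberPhenotype.THIN_LINEAR if positive else FiberPhenotype.THICK_CURLY,
            seed=derive_seed(seed, i),
            **((pos_overrides if positive else neg_overrides) or {}),
        )
        tiles.append(generate_fiber_tile(spec, matrix=matrix))
    return LabeledTileset(tiles=tiles, labels=labels)


@dataclass
class TmaLayout:
    """Core manifest of a tissue microarray.

    ``manifest`` columns: core_id, patient_id, sample_label, slide.
    """

    manifest: pd.DataFrame
    n_patients: int
    n_samples: int
    n_cores: int

    @property
    def total_cores(self) -> int:
        return len(self.manifest)


def generate_tma_layout(n_patients: int = 42, n_samples: int = 3, n_cores: int = 3) -> TmaLayout:
    """Build a TMA manifest with patients split as evenly as possible
    across two slides (42/3/3 -> 378 cores, 21 patients per slide)."""
    if min(n_patients, n_samples, n_cores) < 1:
        raise ValueError("all layout counts must be >= 1")
    if n_samples <= len(SAMPLE_LABELS):
        labels = SAMPLE_LABELS[:n_samples]
    else:
        labels = SAMPLE_LABELS + tuple(f"SAMPLE_{i}" for i in range(len(SAMPLE_LABELS) + 1, n_samples + 1))
    half = (n_patients + 1) // 2
    rows = []
    for p in range(n_patients):
        patient_id = f"P{p + 1:03d}"
        slide = 1 if p < half else 2
        for label in labels:
            for c in range(1, n_cores + 1):
                rows.append(
                    {
                        "core_id": f"{patient_id}_{label}_{c}",
                        "patient_id": patient_id,
                        "sample_label": label,
                        "slide": slide,
                    }
                )
    return TmaLayout(manifest=pd.DataFrame(rows), n_patients=n_patients, n_samples=n_samples, n_cores=n_cores)


@dataclass(frozen=True)
class CoreTruth:
    """Ground-truth composition of one synthetic core.

    Cell-type fractions must sum to 1.  ``marker_pos`` holds the fraction
    of fibroblasts positive for each DAB marker; ``cd8_frac_stroma`` /
    ``cd8_frac_cancer`` are the CD8+ fractions among all cells of each
    compartment.  Fibroblasts sit in STROMA, epithelial cells in CANCER,
    immune cells split by ``immune_stroma_fraction``.
    """

    f_fibroblast: float = 0.35
    f_epithelial: float = 0.50
    f_immune: float = 0.15
    marker_pos: dict = field(
        default_factory=lambda: {"col11a1": 0.30, "asma": 0.45, "pdpn": 0.25}
    )
    cd8_frac_stroma: float = 0.05
    cd8_frac_cancer: float = 0.01
    n_cells: int = 1200
    immune_stroma_fraction: float = 0.5

    def __post_init__(self) -> None:
        fracs = [self.f_fibroblast, self.f_epithelial, self.f_immune]
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("cell-type fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("cell-type fractions must sum to 1")
        for name, frac in {
            **self.marker_pos,
            "cd8_frac_stroma": self.cd8_frac_stroma,
            "cd8_frac_cancer": self.cd8_frac_cancer,
            "immune_stroma_fraction": self.immune_stroma_fraction,
        }.items():
            if frac < 0 or frac > 1:
                raise ValueError(f"fraction {name}={frac} outside [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


# DAB intensity model: marker-positive cells ~ N(0.60, 0.10), negative
# fibroblasts ~ N(0.08, 0.04), other cells ~ N(0.05, 0.03), clipped at 0.
# A threshold of 0.3 (the quantification default) sits >3 SD from both
# modes, so thresholding recovers the positive fraction in expectation.
_DAB_POS = (0.60, 0.10)
_DAB_NEG = (0.08, 0.04)
_DAB_OTHER = (0.05, 0.03)


def generate_cell_table(truth: CoreTruth, seed: int = 0) -> pd.DataFrame:
    """Emulate a cell-detection export for one core.

    Returns a DataFrame with columns ``cell_id, x, y, cell_type,
    compartment, dab_col11a1, dab_asma, dab_pdpn, cd8_positive``.
    """
    rng = np.random.default_rng(seed)
    n = truth.n_cells
    types = rng.choice(
        np.array(["FIBROBLAST", "EPITHELIAL", "IMMUNE"]),
        size=n,
        p=[truth.f_fibroblast, truth.f_epithelial, truth.f_immune],
    )
    compartment = np.where(types == "EPITHELIAL", "CANCER", "STROMA")
    immune = types == "IMMUNE"
    imm_to_cancer = immune & (rng.random(n) >= truth.immune_stroma_fraction)
    compartment = np.where(imm_to_cancer, "CANCER", compartment)

    xy = rng.uniform(0, 1000.0, size=(n, 2))

    fib = types == "FIBROBLAST"
    dab = {}
    for marker, frac in truth.marker_pos.items():
        pos = fib & (rng.random(n) < frac)
        vals = rng.normal(*_DAB_OTHER, size=n)
        vals[fib] = rng.normal(*_DAB_NEG, size=int(fib.sum()))
        vals[pos] = rng.normal(*_DAB_POS, size=int(pos.sum()))
        dab[f"dab_{marker}"] = np.clip(vals, 0.0, None)

    cd8 = np.zeros(n, dtype=bool)
    for comp, frac in (("STROMA", truth.cd8_frac_stroma), ("CANCER", truth.cd8_frac_cancer)):
        in_comp = compartment == comp
        imm_comp = in_comp & immune
        n_imm = int(imm_comp.sum())
        if n_imm == 0:
            continue
        p = min(1.0, frac * int(in_comp.sum()) / n_imm)
        cd8[imm_comp] = rng.random(n_imm) < p

    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "cell_type": types,
            "compartment": compartment,
            **dab,
            "cd8_positive": cd8,
        },
        columns=CELL_TABLE_COLUMNS,
    )


@dataclass(frozen=True)
class CohortScenario:
    """Study conditions for a synthetic cohort.

    ``infiltration_prob`` gives, per sample label and compartment, the
    probability that a tumor is CD8-infiltrated; infiltrated tumors draw
    their CD8+ fraction from ``cd8_infiltrated`` (uniform range, fraction
    units), others from ``cd8_quiescent``.  Primary tumors are less often
    stroma-infiltrated than metastatic/recurrent ones; metastases carry
    more fibroblasts and COL11A1+ CAFs.
    """

    infiltration_prob: dict = field(
        default_factory=lambda: {
            ("PRIMARY", "STROMA"): 0.60,
            ("METASTASIS", "STROMA"): 0.85,
            ("RECURRENCE", "STROMA"): 0.85,
            ("PRIMARY", "CANCER"): 0.40,
            ("METASTASIS", "CANCER"): 0.50,
            ("RECURRENCE", "CANCER"): 0.50,
        }
    )
    cd8_infiltrated: tuple[float, float] = (0.035, 0.12)
    cd8_quiescent: tuple[float, float] = (0.0, 0.015)
    composition: dict = field(
        default_factory=lambda: {
            "PRIMARY": (0.30, 0.55, 0.15),
            "METASTASIS": (0.38, 0.44, 0.18),
            "RECURRENCE": (0.38, 0.44, 0.18),
        }
    )
    col11a1_pos: dict = field(
        default_factory=lambda: {"PRIMARY": 0.20, "METASTASIS": 0.40, "RECURRENCE": 0.40}
    )
    composition_concentration: float = 200.0
    n_cells_range: tuple[int, int] = (800, 1600)


@dataclass
class SyntheticCohort:
    layout: TmaLayout
    truths: dict  # core_id -> CoreTruth
    tables: dict  # core_id -> DataFrame


def generate_cohort(
    layout: TmaLayout | None = None,
    seed: int = 0,
    scenario: CohortScenario | None = None,
) -> SyntheticCohort:
    """Generate per-core truths and cell tables for a whole TMA.

    Infiltration status and CD8 level are drawn once per (patient,
    sample) so triplicate cores of one tumor share a truth up to
    core-level composition jitter, mirroring triplicate punches from one
    block.
    """
    layout = layout or generate_tma_layout()
    scenario = scenario or CohortScenario()
    rng = np.random.default_rng(derive_seed(seed, 0xC0))
    truths: dict[str, CoreTruth] = {}
    tables: dict[str, pd.DataFrame] = {}
    core_index = {cid: i for i, cid in enumerate(layout.manifest["core_id"])}

    for (patient, sample), group in layout.manifest.groupby(["patient_id", "sample_label"], sort=True):
        cd8 = {}
        for comp in ("STROMA", "CANCER"):
            p_inf = scenario.infiltration_prob.get((sample, comp), 0.5)
            rng_range = scenario.cd8_infiltrated if rng.random() < p_inf else scenario.cd8_quiescent
            cd8[comp] = rng.uniform(*rng_range)
        base = np.asarray(scenario.composition.get(sample, (0.35, 0.5, 0.15)))
        col11a1 = float(np.clip(rng.normal(scenario.col11a1_pos.get(sample, 0.3), 0.05), 0.0, 1.0))
        for core_id in group["core_id"]:
            comp_fracs = rng.dirichlet(base * scenario.composition_concentration)
            truth = CoreTruth(
                f_fibroblast=comp_fracs[0],
                f_epithelial=comp_fracs[1],
                f_immune=comp_fracs[2],
                marker_pos={
                    "col11a1": col11a1,
                    "asma": float(np.clip(rng.normal(0.45, 0.05), 0, 1)),
                    "pdpn": float(np.clip(rng.normal(0.25, 0.05), 0, 1)),
                },
                cd8_frac_stroma=float(np.clip(cd8["STROMA"] * rng.uniform(0.8, 1.2), 0, 1)),
                cd8_frac_cancer=float(np.clip(cd8["CANCER"] * rng.uniform(0.8, 1.2), 0, 1)),
                n_cells=int(rng.integers(*scenario.n_cells_range)),
            )
            truths[core_id] = truth
            tables[core_id] = generate_cell_table(truth, seed=derive_seed(seed, 0xCE, core_index[core_id]))
    return SyntheticCohort(layout=layout, truths=truths, tables=tables)
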