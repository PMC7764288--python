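"""Synthetic cytospin scenes, cell tables, reference lines and cohorts.

Every downstream stage of the pipeline is testable without any microscope
or patient data: this module plants cells with known per-channel
integrated intensities into a multichannel image (or emits the equivalent
measurement table directly, skipping imaging), and simulates patient
cohorts with survival times drawn from a proportional-hazards model with
known covariate effects.

Cells are rendered as a disk nucleus inside a larger cell disk: DAPI is
painted on the nucleus, keratins/vimentin/PD-L1 on the whole cell disk,
and CD45 is a binary mask covering CD45+ cells (the positivity readout of
the immunocytochemistry stain; no chromogen optics are simulated).
Cluster members are placed with centers 1.8 nucleus radii apart so their
masks touch after segmentation.  The forward model applies, in order:
background, Gaussian blur, optional Poisson noise, additive Gaussian
noise, and clipping at zero.

The default per-class intensity model mirrors the two calibration
reference lines: epithelial CTCs draw vim/ker ratios log-uniformly in
[0.01, 0.28] and PD-L1 CTCF in [10, 40]; mesenchymal CTCs draw ratios in
[0.88, 22.5] and PD-L1 in [60, 350]; PBMC distractors are CD45+,
keratin-negative, vimentin- and PD-L1-expressing.  Sampling the ratio
directly (vimentin = ratio x keratin) guarantees every generated cell of
a class lies inside that class's calibration range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .quantify import CHANNELS, ChannelStack

__all__ = [
    "LogNormalIntensity",
    "LogUniformRange",
    "CellClassModel",
    "SceneSpec",
    "CohortSimSpec",
    "default_class_models",
    "render_scene",
    "sample_cell_table",
    "sample_reference_line",
    "simulate_cohort",
    "simulate_survival_for_profiles",
    "GROUND_TRUTH_COLUMNS",
]

#: Cluster id used for unclustered cells in ground-truth tables.
SINGLE_ID = 0

GROUND_TRUTH_COLUMNS = (
    "cell_id", "class", "x", "y", "cluster_id", "cd45",
    "tru_intden_dapi", "tru_intden_ker", "tru_intden_vim", "tru_intden_pdl1",
)


@dataclass(frozen=True)
class LogNormalIntensity:
    """Log-normal intensity parameterised by median and geometric SD."""

    median: float
    gsd: float = 1.0

    def __post_init__(self) -> None:
        if self.median <= 0 or self.gsd < 1.0:
            raise ValueError("median must be > 0 and gsd >= 1")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.gsd == 1.0:
            return np.full(n, self.median)
        return self.median * np.exp(math.log(self.gsd) * rng.standard_normal(n))


@dataclass(frozen=True)
class LogUniformRange:
    """Log-uniform draw over a closed interval [lo, hi], lo > 0."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo <= self.hi):
            raise ValueError(f"need 0 < lo <= hi, got ({self.lo}, {self.hi})")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.uniform(math.log(self.lo), math.log(self.hi), n))


@dataclass(frozen=True)
class CellClassModel:
    """Intensity model of one cell class.

    Vimentin is specified either directly (``vim``) or through the
    vim/ker CTCF ratio (``vim_ker_ratio``), in which case each cell's
    vimentin intensity is ratio x keratin intensity, pinning the measured
    ratio to the configured range.
    """

    dapi: LogNormalIntensity
    ker: LogNormalIntensity
    pdl1: LogUniformRange | LogNormalIntensity
    vim: LogNormalIntensity | None = None
    vim_ker_ratio: LogUniformRange | None = None
    cd45_positive: bool = False

    def __post_init__(self) -> None:
        if (self.vim is None) == (self.vim_ker_ratio is None):
            raise ValueError("specify exactly one of vim or vim_ker_ratio")

    def sample(self, rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
        ker = self.ker.sample(rng, n)
        if self.vim_ker_ratio is not None:
            vim = self.vim_ker_ratio.sample(rng, n) * ker
        else:
            vim = self.vim.sample(rng, n)
        return {
            "dapi": self.dapi.sample(rng, n),
            "ker": ker,
            "vim": vim,
            "pdl1": self.pdl1.sample(rng, n),
        }


def default_class_models() -> dict[str, CellClassModel]:
    """Default intensity models for the three study populations.

    CTC classes draw vim/ker ratios and PD-L1 CTCF log-uniformly over the
    packaged calibration ranges of their reference line; PBMCs are CD45+,
    essentially keratin-negative, and vimentin/PD-L1 expressing.
    """
    return {
        "epithelial-CTC": CellClassModel(
            dapi=LogNormalIntensity(50_000, 1.2),
            ker=LogNormalIntensity(400, 1.4),
            vim_ker_ratio=LogUniformRange(0.01, 0.28),
            pdl1=LogUniformRange(10, 40),
            cd45_positive=False,
        ),
        "mesenchymal-CTC": CellClassModel(
            dapi=LogNormalIntensity(50_000, 1.2),
            ker=LogNormalIntensity(150, 1.4),
            vim_ker_ratio=LogUniformRange(0.88, 22.5),
            pdl1=LogUniformRange(60, 350),
            cd45_positive=False,
        ),
        "pbmc": CellClassModel(
            dapi=LogNormalIntensity(30_000, 1.2),
            ker=LogNormalIntensity(0.5, 1.5),
            vim=LogNormalIntensity(80, 1.6),
            pdl1=LogNormalIntensity(30, 1.8),
            cd45_positive=True,
        ),
    }


@dataclass(frozen=True)
class SceneSpec:
    """Specification of one synthetic cytospin field.

    ``n_cells_per_class`` counts *single* cells; cluster members declared
    in ``cluster_spec`` (list of ``(class_name, size >= 2)``) are
    additional.  All randomness flows from ``seed``.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    n_cells_per_class: dict = field(
        default_factory=lambda: {"epithelial-CTC": 4, "mesenchymal-CTC": 4, "pbmc": 30}
    )
    cluster_spec: tuple = ()
    intensity_model: dict = field(default_factory=default_class_models)
    nucleus_radius_px: float = 5.0
    cell_radius_px: float = 9.0
    background_level: dict = field(
        default_factory=lambda: {"dapi": 2.0, "ker": 2.0, "vim": 2.0, "pdl1": 2.0}
    )
    psf_sigma_px: float = 1.0
    gaussian_noise_sd: float = 1.0
    use_poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if any(n < 0 for n in self.n_cells_per_class.values()):
            raise ValueError("cell counts must be nonnegative")
        for cls, size in self.cluster_spec:
            if size < 2:
                raise ValueError(f"cluster size must be >= 2, got {size} for {cls}")
            if cls not in self.intensity_model:
                raise ValueError(f"cluster class {cls!r} has no intensity model")
        for cls in self.n_cells_per_class:
            if cls not in self.intensity_model:
                raise ValueError(f"class {cls!r} has no intensity model")
        if self.nucleus_radius_px <= 0 or self.cell_radius_px < self.nucleus_radius_px:
            raise ValueError("need 0 < nucleus_radius_px <= cell_radius_px")
        if any(v < 0 for v in self.background_level.values()):
            raise ValueError("background levels must be nonnegative")
        if self.psf_sigma_px < 0 or self.gaussian_noise_sd < 0:
            raise ValueError("noise parameters must be nonnegative")


def _place_cells(spec: SceneSpec, rng: np.random.Generator, max_tries: int = 5000):
    """Place cluster chains then singles without inter-cell overlap.

    Returns a list of (class_name, cx, cy, cluster_id).  Cluster members
    are chained with centers 1.8 nucleus radii apart (touching after
    segmentation); distinct cells/clusters keep their cell disks at least
    a 4 px gap apart.  Raises RuntimeError when a placement cannot be
    found within the retry budget, reporting the achieved density.
    """
    H, W = spec.image_height_px, spec.image_width_px
    r_cell = spec.cell_radius_px
    step = 1.8 * spec.nucleus_radius_px
    margin = r_cell + 4
    if W - 2 * margin <= 0 or H - 2 * margin <= 0:
        raise RuntimeError(f"image {H}x{W} too small for cells of radius {r_cell}")
    gap = 4.0
    min_sep = 2 * r_cell + gap

    placed_xy: list[tuple[float, float]] = []
    out: list[tuple[str, float, float, int]] = []

    def far_enough(pts: list[tuple[float, float]]) -> bool:
        if not placed_xy:
            return True
        existing = np.asarray(placed_xy)
        cand = np.asarray(pts)
        d2 = ((existing[:, None, :] - cand[None, :, :]) ** 2).sum(-1)
        return bool((d2 >= min_sep**2).all())

    def in_bounds(pts: list[tuple[float, float]]) -> bool:
        return all(margin <= x <= W - margin and margin <= y <= H - margin for x, y in pts)

    cluster_id = 0
    for cls, size in spec.cluster_spec:
        cluster_id += 1
        for _ in range(max_tries):
            x0 = rng.uniform(margin, W - margin)
            y0 = rng.uniform(margin, H - margin)
            theta = rng.uniform(0, 2 * math.pi)
            pts = [
                (x0 + k * step * math.cos(theta), y0 + k * step * math.sin(theta))
                for k in range(size)
            ]
            if in_bounds(pts) and far_enough(pts):
                placed_xy.extend(pts)
                out.extend((cls, x, y, cluster_id) for x, y in pts)
                break
        else:
            raise RuntimeError(
                f"failed to place a {size}-cell {cls} cluster after {max_tries} tries; "
                f"achieved {len(placed_xy)} cells on {H}x{W}"
            )

    for cls in sorted(spec.n_cells_per_class):
        for _ in range(spec.n_cells_per_class[cls]):
            for _ in range(max_tries):
                x0 = rng.uniform(margin, W - margin)
                y0 = rng.uniform(margin, H - margin)
                if far_enough([(x0, y0)]):
                    placed_xy.append((x0, y0))
                    out.append((cls, x0, y0, SINGLE_ID))
                    break
            else:
                raise RuntimeError(
                    f"failed to place a {cls} cell after {max_tries} tries; "
                    f"achieved {len(placed_xy)} cells on {H}x{W}"
                )
    return out


def _disk_mask(H: int, W: int, cx: float, cy: float, radius: float) -> np.ndarray:
    y0 = max(0, int(cy - radius) - 1)
    y1 = min(H, int(cy + radius) + 2)
    x0 = max(0, int(cx - radius) - 1)
    x1 = min(W, int(cx + radius) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    local = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    mask = np.zeros((H, W), dtype=bool)
    mask[y0:y1, x0:x1] = local
    return mask


def _draw_ground_truth(spec: SceneSpec, rng: np.random.Generator, placements) -> pd.DataFrame:
    rows = []
    by_class: dict[str, list[int]] = {}
    for i, (cls, _, _, _) in enumerate(placements):
        by_class.setdefault(cls, []).append(i)
    intens = [None] * len(placements)
    for cls in sorted(by_class):
        idx = by_class[cls]
        draws = spec.intensity_model[cls].sample(rng, len(idx))
        for j, i in enumerate(idx):
            intens[i] = {c: float(draws[c][j]) for c in CHANNELS}
    for i, (cls, x, y, cid) in enumerate(placements):
        rows.append(
            {
                "cell_id": i + 1,
                "class": cls,
                "x": x,
                "y": y,
                "cluster_id": cid,
                "cd45": bool(spec.intensity_model[cls].cd45_positive),
                **{f"tru_intden_{c}": intens[i][c] for c in CHANNELS},
            }
        )
    return pd.DataFrame(rows, columns=list(GROUND_TRUTH_COLUMNS))


def render_scene(spec: SceneSpec) -> tuple[ChannelStack, pd.DataFrame]:
    """Render one synthetic cytospin field.

    Returns the channel stack and a ground-truth table with one row per
    planted cell carrying its true (pre-blur, pre-noise) integrated
    intensity per channel.  Identical spec + seed gives bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    placements = _place_cells(spec, rng)
    truth = _draw_ground_truth(spec, rng, placements)

    H, W = spec.image_height_px, spec.image_width_px
    planes = {c: np.zeros((H, W), dtype=float) for c in CHANNELS}
    cd45 = np.zeros((H, W), dtype=np.uint8)

    for row in truth.itertuples(index=False):
        cell_mask = _disk_mask(H, W, row.x, row.y, spec.cell_radius_px)
        nuc_mask = _disk_mask(H, W, row.x, row.y, spec.nucleus_radius_px)
        n_cell = int(cell_mask.sum())
        n_nuc = int(nuc_mask.sum())
        planes["dapi"][nuc_mask] += row.tru_intden_dapi / n_nuc
        for c in ("ker", "vim", "pdl1"):
            planes[c][cell_mask] += getattr(row, f"tru_intden_{c}") / n_cell
        if row.cd45:
            cd45[cell_mask] = 1

    for c in CHANNELS:
        img = planes[c] + spec.background_level.get(c, 0.0)
        if spec.psf_sigma_px > 0:
            img = gaussian_filter(img, spec.psf_sigma_px)
        if spec.use_poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if spec.gaussian_noise_sd > 0:
            img = img + rng.normal(0.0, spec.gaussian_noise_sd, img.shape)
        planes[c] = np.clip(img, 0.0, None)

    stack = ChannelStack(
        dapi=planes["dapi"], ker=planes["ker"], vim=planes["vim"],
        pdl1=planes["pdl1"], cd45mask=cd45,
    )
    return stack, truth


def sample_cell_table(spec: SceneSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Image-free fast path: draw per-cell CTCF tables directly.

    Cell positions are placed exactly as in :func:`render_scene`, but the
    measured CTCF values equal the drawn intensities (zero background, no
    optics).  Returns a cell table shaped like the output of
    :func:`~ctcpheno.quantify.quantify_sample` plus the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    placements = _place_cells(spec, rng)
    truth = _draw_ground_truth(spec, rng, placements)

    area = int(_disk_mask(
        int(4 * spec.cell_radius_px + 4), int(4 * spec.cell_radius_px + 4),
        2 * spec.cell_radius_px, 2 * spec.cell_radius_px, spec.cell_radius_px,
    ).sum())
    cells = pd.DataFrame(
        {
            "cell_id": truth["cell_id"],
            "sample_id": "synthetic",
            "x": truth["x"],
            "y": truth["y"],
            "area_px": area,
            **{f"intden_{c}": truth[f"tru_intden_{c}"] for c in ("ker", "vim", "pdl1")},
            **{f"mean_bg_{c}": 0.0 for c in ("ker", "vim", "pdl1")},
            **{f"ctcf_{c}": truth[f"tru_intden_{c}"] for c in ("ker", "vim", "pdl1")},
            "dapi_positive": True,
            "cd45_positive": truth["cd45"],
        }
    )
    return cells, truth


def sample_reference_line(
    line: str,
    n_cells: int = 120,
    *,
    seed: int = 0,
    model: CellClassModel | None = None,
):
    """Draw a synthetic reference cell-line population for calibration.

    ``line`` selects a default class model: ``"epithelial"`` (MCF-7-like)
    or ``"mesenchymal"`` (MDA-MB-231-like).  Returns a
    :class:`~ctcpheno.calibrate.ReferenceDistribution`.
    """
    from .calibrate import ReferenceDistribution

    if model is None:
        key = {"epithelial": "epithelial-CTC", "mesenchymal": "mesenchymal-CTC"}.get(line)
        if key is None:
            raise ValueError(f"unknown reference line kind {line!r}")
        model = default_class_models()[key]
    rng = np.random.default_rng(seed)
    draws = model.sample(rng, n_cells)
    return ReferenceDistribution(
        line_name=line,
        vim_ker_ratios=draws["vim"] / draws["ker"],
        pdl1_ctcf=draws["pdl1"],
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimSpec:
    """Specification of a synthetic patient cohort.

    Binary covariates (subpopulation presence flags) are drawn from
    ``prevalence``; event times follow a proportional-hazards model with
    the given baseline (``{"dist": "exponential", "rate_per_month": r}``
    or ``{"dist": "weibull", "shape": k, "scale_months": s}``) and
    per-covariate log hazard ratios.  Random censoring targets an overall
    ``censoring_rate``; administrative censoring applies at the follow-up
    horizon.
    """

    n_patients: int = 100
    prevalence: dict = field(default_factory=lambda: {"has_cluster_mctc": 0.3})
    baseline_hazard: dict = field(
        default_factory=lambda: {"dist": "exponential", "rate_per_month": 0.06}
    )
    log_hazard_ratios: dict = field(default_factory=dict)
    censoring_rate: float = 0.0
    followup_horizon_months: float = 60.0
    seed: int = 0
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not all(0.0 <= p <= 1.0 for p in self.prevalence.values()):
            raise ValueError("prevalences must be in [0, 1]")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.followup_horizon_months <= 0:
            raise ValueError("follow-up horizon must be positive")
        unknown = set(self.log_hazard_ratios) - set(self.prevalence)
        if unknown:
            raise ValueError(f"log_hazard_ratios reference unknown covariates: {sorted(unknown)}")
        dist = self.baseline_hazard.get("dist")
        if dist not in ("exponential", "weibull"):
            raise ValueError(f"unsupported baseline hazard {dist!r}")


def _baseline_times(baseline: dict, e_std: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Invert the cumulative hazard: T = H0^{-1}(E / exp(eta))."""
    u = e_std / np.exp(eta)
    if baseline["dist"] == "exponential":
        return u / float(baseline["rate_per_month"])
    shape = float(baseline["shape"])
    scale = float(baseline["scale_months"])
    return scale * u ** (1.0 / shape)


def _marginal_event_rate(baseline: dict) -> float:
    if baseline["dist"] == "exponential":
        return float(baseline["rate_per_month"])
    # Weibull: use 1/mean as an effective rate for the censoring target.
    shape = float(baseline["shape"])
    scale = float(baseline["scale_months"])
    return 1.0 / (scale * math.gamma(1.0 + 1.0 / shape))


def _censoring_hazard(baseline: dict, eta: np.ndarray, rate: float) -> float:
    """Exponential censoring hazard targeting an overall censoring fraction.

    For exponential event times with per-subject rates lam_i the marginal
    censoring probability under Exp(mu) censoring is mean_i mu/(mu+lam_i);
    solve that for mu.  Weibull baselines fall back to an effective-rate
    approximation (1/mean event time)."""
    from scipy.optimize import brentq

    lam_eff = _marginal_event_rate(baseline)
    if baseline["dist"] == "exponential":
        lam_i = lam_eff * np.exp(eta)

        def frac(mu: float) -> float:
            return float(np.mean(mu / (mu + lam_i))) - rate

        hi = lam_i.max() * rate / (1 - rate) + lam_eff
        while frac(hi) < 0:
            hi *= 2
        return brentq(frac, 1e-12, hi)
    return lam_eff * rate / (1.0 - rate)


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Simulate one cohort of survival records with known ground truth.

    Returns a table with columns ``patient_id``, ``endpoint``,
    ``time_months``, ``event`` and one 0/1 column per covariate.  Records
    carry the true covariate values so effect recovery can be tested.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    cov = {name: (rng.random(n) < p).astype(int) for name, p in sorted(spec.prevalence.items())}
    eta = np.zeros(n)
    for name, beta in spec.log_hazard_ratios.items():
        eta = eta + beta * cov[name]

    t_event = _baseline_times(spec.baseline_hazard, rng.exponential(1.0, n), eta)
    c_time = np.full(n, spec.followup_horizon_months)
    if spec.censoring_rate > 0:
        mu = _censoring_hazard(spec.baseline_hazard, eta, spec.censoring_rate)
        c_time = np.minimum(c_time, rng.exponential(1.0 / mu, n))

    time = np.minimum(t_event, c_time)
    event = (t_event <= c_time).astype(int)
    if event.sum() == 0:
        warnings.warn("degenerate cohort: all records censored", stacklevel=2)

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "endpoint": spec.endpoint,
            "time_months": time,
            "event": event,
            **cov,
        }
    )
    return df


def simulate_survival_for_profiles(
    covariates: pd.DataFrame,
    *,
    log_hazard_ratios: dict,
    baseline_hazard: dict | None = None,
    censoring_rate: float = 0.0,
    followup_horizon_months: float = 60.0,
    seed: int = 0,
    endpoint: str = "OS",
) -> pd.DataFrame:
    """Draw survival times conditional on observed covariates.

    ``covariates`` must carry ``patient_id`` plus the 0/1 columns named in
    ``log_hazard_ratios``.  Used by the pipeline to couple simulated
    clinical outcomes to the CTC profiles actually measured on each
    synthetic patient.
    """
    baseline = baseline_hazard or {"dist": "exponential", "rate_per_month": 0.06}
    rng = np.random.default_rng(seed)
    n = len(covariates)
    eta = np.zeros(n)
    for name, beta in log_hazard_ratios.items():
        eta = eta + beta * covariates[name].to_numpy(dtype=float)

    t_event = _baseline_times(baseline, rng.exponential(1.0, n), eta)
    c_time = np.full(n, followup_horizon_months)
    if censoring_rate > 0:
        mu = _censoring_hazard(baseline, eta, censoring_rate)
        c_time = np.minimum(c_time, rng.exponential(1.0 / mu, n))
    time = np.minimum(t_event, c_time)
    event = (t_event <= c_time).astype(int)
    return pd.DataFrame(
        {
            "patient_id": covariates["patient_id"].to_numpy(),
            "endpoint": endpoint,
            "time_months": time,
            "event": event,
        }
    )
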