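"""CTC identification, EMT / PD-L1 calls, clusters, and patient profiles.

A circulating tumor cell is a DAPI-positive, keratin-positive, CD45-
negative cell.  Keratin positivity has no published numeric cutoff, so by
default it is self-calibrated per sample: the 99th percentile of keratin
CTCF among the sample's CD45+ cells (the built-in negative control
population), floored at zero.  A constant override is available.

Each CTC is then scored on two axes against a
:class:`~ctcpheno.calibrate.CalibrationModel`:

* EMT: vim/ker ratio (vimentin CTCF / keratin CTCF).  Ratios up to the
  threshold (default 0.88, the mesenchymal reference range's lower
  bound) are epithelial (eCTC); greater ratios are mesenchymal (mCTC).
  A negative vimentin CTCF clamps the ratio to 0 (vimentin-negative).
* PD-L1: CTCF up to the threshold (default 40, the epithelial reference
  range's upper bound) is negative/low, above it positive.  Values in
  the inter-range gap (default 40-60) are called positive under the
  strict greater-than reading but flagged for sensitivity analysis.

Clusters are connected components of the touching graph among CTCs
(masks dilated by an adjacency margin intersect, or centroids within a
distance cutoff); components of two or more cells are clusters, the rest
singles.  CD45+ cells never join clusters.  Patient-level aggregation
counts each subpopulation (single/cluster x eCTC/mCTC x PD-L1 status)
and derives presence flags, including mesenchymal predominance (mCTCs
make up at least 50% of the patient's CTCs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.morphology import disk

from .calibrate import CalibrationModel, DEFAULT_CALIBRATION

__all__ = [
    "SINGLETON_ID",
    "PhenotypeCall",
    "ClusterAssignment",
    "PatientCTCProfile",
    "keratin_positivity_cutoff",
    "identify_ctc",
    "classify_emt",
    "classify_pdl1",
    "classify_cells",
    "assign_clusters",
    "quartile_strata",
    "aggregate_patient_profile",
    "compare_timepoints",
    "PROFILE_COUNTS",
    "PROFILE_FLAGS",
]

#: Reserved cluster id carried by all unclustered CTCs.
SINGLETON_ID = 0


@dataclass(frozen=True)
class PhenotypeCall:
    """Per-cell classification result."""

    cell_id: int
    is_ctc: bool
    vim_ker_ratio: float  # NaN for non-CTCs
    emt_class: str  # "eCTC" | "mCTC" | "NA"
    pdl1_class: str  # "negative_low" | "positive" | "NA"
    pdl1_gap_flag: bool
    quartile_stratum: str = "NA"  # "LQ" | "MID" | "HQ" | "NA"


@dataclass
class ClusterAssignment:
    """Partition of the CTC set into clusters and singles.

    ``cell_to_cluster`` maps every CTC's cell_id to a cluster id; singles
    carry the reserved :data:`SINGLETON_ID`.  ``clusters`` maps each
    cluster id (>= 1, size >= 2) to its member cell_ids.
    """

    cell_to_cluster: dict
    clusters: dict

    def __post_init__(self) -> None:
        for cid, members in self.clusters.items():
            if len(members) < 2:
                raise ValueError(f"cluster {cid} has fewer than 2 members")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def is_clustered(self, cell_id) -> bool:
        return self.cell_to_cluster.get(cell_id, SINGLETON_ID) != SINGLETON_ID


def keratin_positivity_cutoff(
    cells: pd.DataFrame, *, quantile: float = 0.99, override: float | None = None
) -> float:
    """Self-calibrated keratin positivity cutoff for one sample.

    The cutoff is the ``quantile`` (default 99th percentile) of keratin
    CTCF among the sample's CD45+ cells, floored at 0.  With no CD45+
    cells the floor (0) is returned.  ``override`` short-circuits the
    calibration with a constant.
    """
    if override is not None:
        return float(override)
    neg = cells.loc[cells["cd45_positive"].astype(bool), "ctcf_ker"]
    if len(neg) == 0:
        return 0.0
    return float(max(0.0, np.quantile(neg.to_numpy(dtype=float), quantile)))


def identify_ctc(dapi_positive, ctcf_ker, cd45_positive, keratin_cutoff: float):
    """CTC rule: DAPI-positive AND keratin CTCF above cutoff AND CD45-negative.

    Vectorized; accepts scalars or arrays.
    """
    return (
        np.asarray(dapi_positive, dtype=bool)
        & (np.asarray(ctcf_ker, dtype=float) > keratin_cutoff)
        & ~np.asarray(cd45_positive, dtype=bool)
    )


def classify_emt(
    ctcf_vim: float, ctcf_ker: float, calib: CalibrationModel = DEFAULT_CALIBRATION
) -> tuple[float, str]:
    """EMT call for one CTC: returns (vim/ker ratio, class).

    Ratios up to the threshold are eCTC, greater are mCTC; a negative
    vimentin CTCF clamps the ratio to 0 (vimentin-negative, hence
    epithelial).  Callers must not pass non-CTCs: keratin CTCF <= 0 is an
    error.
    """
    if ctcf_ker <= 0:
        raise ValueError(
            f"keratin CTCF must be positive to form a vim/ker ratio, got {ctcf_ker}"
        )
    ratio = max(0.0, float(ctcf_vim)) / float(ctcf_ker)
    emt_class = "eCTC" if ratio <= calib.emt_ratio_threshold else "mCTC"
    return ratio, emt_class


def classify_pdl1(
    ctcf_pdl1: float, calib: CalibrationModel = DEFAULT_CALIBRATION
) -> tuple[str, bool]:
    """PD-L1 call: (class, gap_flag).

    Values up to the threshold are negative/low, above it positive; the
    gap flag marks values strictly between the negative range's upper and
    the positive range's lower bound (ambiguous zone between the two
    reference populations).
    """
    value = float(ctcf_pdl1)
    pdl1_class = "negative_low" if value <= calib.pdl1_threshold else "positive"
    gap = calib.pdl1_negative_range[1] < value < calib.pdl1_positive_range[0]
    return pdl1_class, gap


def quartile_strata(ratios) -> np.ndarray:
    """Low/high-quartile strata of the vim/ker ratio distribution.

    Quartiles are computed over the supplied ratios (the whole analysis
    set, not per patient) with linear interpolation.  A cell is LQ when
    its ratio <= Q1 and HQ when >= Q3, otherwise MID.  Degenerate cases:
    fewer than 4 ratios -> all NA; a cell qualifying for both ends
    (possible only when Q1 == Q3) is tie-broken to MID with a warning.
    """
    arr = np.asarray(ratios, dtype=float)
    out = np.full(arr.shape, "NA", dtype=object)
    if arr.size < 4:
        return out
    q1, q3 = np.quantile(arr, [0.25, 0.75], method="linear")
    lq = arr <= q1
    hq = arr >= q3
    both = lq & hq
    if both.any():
        warnings.warn(
            "degenerate quartiles (Q1 == Q3): ambiguous cells assigned to MID",
            stacklevel=2,
        )
    out[:] = "MID"
    out[lq & ~both] = "LQ"
    out[hq & ~both] = "HQ"
    return out


def classify_cells(
    cells: pd.DataFrame,
    calib: CalibrationModel = DEFAULT_CALIBRATION,
    *,
    keratin_cutoff: float | None = None,
    compute_quartiles: bool = True,
) -> pd.DataFrame:
    """Classify every cell of a measurement table.

    ``cells`` is a table shaped like the output of
    :func:`~ctcpheno.quantify.quantify_sample` (columns ``cell_id``,
    ``ctcf_ker``, ``ctcf_vim``, ``ctcf_pdl1``, ``dapi_positive``,
    ``cd45_positive``).  Returns one row per input cell with columns
    ``cell_id``, ``is_ctc``, ``vim_ker_ratio``, ``emt_class``,
    ``pdl1_class``, ``pdl1_gap_flag``, ``quartile_stratum``.  Non-CTCs
    receive NA classes and a NaN ratio.
    """
    cutoff = keratin_positivity_cutoff(cells, override=keratin_cutoff)
    is_ctc = identify_ctc(
        cells["dapi_positive"], cells["ctcf_ker"], cells["cd45_positive"], cutoff
    )

    n = len(cells)
    ratio = np.full(n, np.nan)
    emt = np.full(n, "NA", dtype=object)
    pdl1 = np.full(n, "NA", dtype=object)
    gap = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(np.asarray(is_ctc)):
        r, e = classify_emt(cells["ctcf_vim"].iat[i], cells["ctcf_ker"].iat[i], calib)
        ratio[i], emt[i] = r, e
        pdl1[i], gap[i] = classify_pdl1(cells["ctcf_pdl1"].iat[i], calib)

    strata = np.full(n, "NA", dtype=object)
    if compute_quartiles:
        ctc_idx = np.flatnonzero(np.asarray(is_ctc))
        if ctc_idx.size:
            strata[ctc_idx] = quartile_strata(ratio[ctc_idx])

    return pd.DataFrame(
        {
            "cell_id": cells["cell_id"].to_numpy(),
            "is_ctc": np.asarray(is_ctc, dtype=bool),
            "vim_ker_ratio": ratio,
            "emt_class": emt,
            "pdl1_class": pdl1,
            "pdl1_gap_flag": gap,
            "quartile_stratum": strata,
        }
    )


def _mask_adjacency_edges(ctc_ids, label_image: np.ndarray, adjacency_px: int):
    """Edges between CTC labels whose masks, dilated, intersect."""
    footprint = disk(max(1, int(adjacency_px)))
    bboxes = {}
    from scipy import ndimage as ndi

    objects = ndi.find_objects(label_image)
    for cid in ctc_ids:
        sl = objects[int(cid) - 1]
        if sl is not None:
            bboxes[cid] = sl
    edges = []
    pad = int(adjacency_px) + 1
    ids = [c for c in ctc_ids if c in bboxes]
    for i, a in enumerate(ids):
        sa = bboxes[a]
        for b in ids[i + 1:]:
            sb = bboxes[b]
            # bbox prefilter: expanded boxes must overlap
            if (
                sa[0].start - pad > sb[0].stop + pad or sb[0].start - pad > sa[0].stop + pad
                or sa[1].start - pad > sb[1].stop + pad or sb[1].start - pad > sa[1].stop + pad
            ):
                continue
            r0 = max(min(sa[0].start, sb[0].start) - pad, 0)
            r1 = min(max(sa[0].stop, sb[0].stop) + pad, label_image.shape[0])
            c0 = max(min(sa[1].start, sb[1].start) - pad, 0)
            c1 = min(max(sa[1].stop, sb[1].stop) + pad, label_image.shape[1])
            window = label_image[r0:r1, c0:c1]
            mask_a = binary_dilation(window == a, structure=footprint)
            if (mask_a & (window == b)).any():
                edges.append((a, b))
    return edges


def _centroid_edges(ctc_ids, centroids: np.ndarray, max_dist: float):
    edges = []
    for i in range(len(ctc_ids)):
        for j in range(i + 1, len(ctc_ids)):
            if np.hypot(*(centroids[i] - centroids[j])) <= max_dist:
                edges.append((ctc_ids[i], ctc_ids[j]))
    return edges


def assign_clusters(
    ctc_ids,
    *,
    label_image: np.ndarray | None = None,
    centroids: np.ndarray | None = None,
    adjacency_px: int = 2,
    max_centroid_distance: float | None = None,
) -> ClusterAssignment:
    """Group CTCs into clusters by physical contact.

    Two CTCs touch when their masks, dilated by ``adjacency_px``,
    intersect (``label_image`` mode: labels are the cell-region label
    image, cell_ids equal label values) or when their centroids are
    within ``max_centroid_distance`` (table mode).  Connected components
    of the touching graph with two or more members are clusters; the rest
    are singles.  Only the supplied CTC ids participate: leukocytes and
    other non-CTCs never join clusters.
    """
    ctc_ids = [int(c) for c in ctc_ids]
    if not ctc_ids:
        return ClusterAssignment(cell_to_cluster={}, clusters={})
    if label_image is not None:
        edges = _mask_adjacency_edges(ctc_ids, label_image, adjacency_px)
    elif centroids is not None:
        if max_centroid_distance is None:
            raise ValueError("centroid mode requires max_centroid_distance")
        edges = _centroid_edges(ctc_ids, np.asarray(centroids, dtype=float), max_centroid_distance)
    else:
        raise ValueError("supply either label_image or centroids")

    index = {c: i for i, c in enumerate(ctc_ids)}
    n = len(ctc_ids)
    if edges:
        rows = [index[a] for a, b in edges]
        cols = [index[b] for a, b in edges]
        graph = coo_matrix((np.ones(len(edges)), (rows, cols)), shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    n_comp, comp = connected_components(graph, directed=False)

    members: dict[int, list[int]] = {}
    for cid, k in zip(ctc_ids, comp):
        members.setdefault(int(k), []).append(cid)

    cell_to_cluster: dict[int, int] = {}
    clusters: dict[int, list[int]] = {}
    next_id = 1
    for k in sorted(members, key=lambda k: min(members[k])):
        cells = sorted(members[k])
        if len(cells) >= 2:
            clusters[next_id] = cells
            for c in cells:
                cell_to_cluster[c] = next_id
            next_id += 1
        else:
            cell_to_cluster[cells[0]] = SINGLETON_ID
    return ClusterAssignment(cell_to_cluster=cell_to_cluster, clusters=clusters)


PROFILE_COUNTS = (
    "total_ctc", "single_ctc", "cluster_ctc_cells", "n_clusters",
    "e_ctc", "m_ctc", "single_m_ctc", "cluster_m_ctc",
    "pdl1pos_m_ctc", "single_pdl1pos_m_ctc", "cluster_pdl1pos_m_ctc",
)
PROFILE_FLAGS = (
    "has_cluster", "has_cluster_mctc", "has_cluster_pdl1pos_mctc",
    "has_single_mctc", "has_single_pdl1pos_mctc", "predominantly_mesenchymal",
)


@dataclass(frozen=True)
class PatientCTCProfile:
    """Per patient x timepoint CTC subpopulation counts and flags."""

    patient_id: str
    timepoint: str  # "D1" | "D8"
    total_ctc: int = 0
    single_ctc: int = 0
    cluster_ctc_cells: int = 0
    n_clusters: int = 0
    e_ctc: int = 0
    m_ctc: int = 0
    single_m_ctc: int = 0
    cluster_m_ctc: int = 0
    pdl1pos_m_ctc: int = 0
    single_pdl1pos_m_ctc: int = 0
    cluster_pdl1pos_m_ctc: int = 0
    has_cluster: bool = False
    has_cluster_mctc: bool = False
    has_cluster_pdl1pos_mctc: bool = False
    has_single_mctc: bool = False
    has_single_pdl1pos_mctc: bool = False
    predominantly_mesenchymal: bool = False

    def __post_init__(self) -> None:
        if self.single_ctc + self.cluster_ctc_cells != self.total_ctc:
            raise ValueError("single_ctc + cluster_ctc_cells must equal total_ctc")
        if self.e_ctc + self.m_ctc > self.total_ctc:
            raise ValueError("e_ctc + m_ctc cannot exceed total_ctc")

    def to_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "timepoint": self.timepoint,
            **{name: getattr(self, name) for name in PROFILE_COUNTS},
            **{name: getattr(self, name) for name in PROFILE_FLAGS},
        }


def aggregate_patient_profile(
    calls: pd.DataFrame,
    assignment: ClusterAssignment,
    patient_id: str,
    timepoint: str = "D1",
) -> PatientCTCProfile:
    """Aggregate per-cell calls into one patient's subpopulation profile.

    ``calls`` is the output of :func:`classify_cells` for one
    patient-timepoint (an optional ``patient_id`` column, if present,
    must be single-valued).  Mesenchymal predominance is
    ``m_ctc / total_ctc >= 0.5`` (false for zero CTCs); the 50% boundary
    counts as predominant.
    """
    if "patient_id" in calls.columns and calls["patient_id"].nunique() > 1:
        raise ValueError(
            f"mixed patient ids in one profile: {sorted(calls['patient_id'].unique())}"
        )

    ctcs = calls.loc[calls["is_ctc"].astype(bool)]
    clustered = ctcs["cell_id"].map(lambda c: assignment.is_clustered(int(c))).astype(bool)
    is_m = (ctcs["emt_class"] == "mCTC").to_numpy()
    is_e = (ctcs["emt_class"] == "eCTC").to_numpy()
    is_pdl1 = (ctcs["pdl1_class"] == "positive").to_numpy()
    clus = clustered.to_numpy()

    total = len(ctcs)
    counts = dict(
        total_ctc=total,
        single_ctc=int((~clus).sum()),
        cluster_ctc_cells=int(clus.sum()),
        n_clusters=assignment.n_clusters,
        e_ctc=int(is_e.sum()),
        m_ctc=int(is_m.sum()),
        single_m_ctc=int((is_m & ~clus).sum()),
        cluster_m_ctc=int((is_m & clus).sum()),
        pdl1pos_m_ctc=int((is_m & is_pdl1).sum()),
        single_pdl1pos_m_ctc=int((is_m & is_pdl1 & ~clus).sum()),
        cluster_pdl1pos_m_ctc=int((is_m & is_pdl1 & clus).sum()),
    )
    flags = dict(
        has_cluster=counts["n_clusters"] > 0,
        has_cluster_mctc=counts["cluster_m_ctc"] > 0,
        has_cluster_pdl1pos_mctc=counts["cluster_pdl1pos_m_ctc"] > 0,
        has_single_mctc=counts["single_m_ctc"] > 0,
        has_single_pdl1pos_mctc=counts["single_pdl1pos_m_ctc"] > 0,
        predominantly_mesenchymal=(total > 0 and counts["m_ctc"] / total >= 0.5),
    )
    return PatientCTCProfile(patient_id=patient_id, timepoint=timepoint, **counts, **flags)


def compare_timepoints(
    profile_d1: PatientCTCProfile, profile_d8: PatientCTCProfile
) -> pd.DataFrame:
    """Per-count signed change from day 1 to day 8 for one patient.

    Returns one row per count with columns ``count``, ``d1``, ``d8``,
    ``delta`` (d8 - d1) and ``trend`` in {increased, decreased,
    unchanged}.
    """
    if profile_d1.patient_id != profile_d8.patient_id:
        raise ValueError(
            f"mismatched patients: {profile_d1.patient_id!r} vs {profile_d8.patient_id!r}"
        )
    rows = []
    for name in PROFILE_COUNTS:
        v1 = getattr(profile_d1, name)
        v8 = getattr(profile_d8, name)
        delta = v8 - v1
        trend = "unchanged" if delta == 0 else ("increased" if delta > 0 else "decreased")
        rows.append(
            {"patient_id": profile_d1.patient_id, "count": name,
             "d1": v1, "d8": v8, "delta": delta, "trend": trend}
        )
    return pd.DataFrame(rows)
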