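"""Cell-line-based calibration of CTC classification thresholds.

The epithelial/mesenchymal status of a circulating tumor cell (CTC) is
scored by the ratio of vimentin to keratin fluorescence (vim/ker, both as
corrected total cell fluorescence, CTCF).  The decision boundary is not a
free parameter: it is anchored to two breast-cancer reference cell lines
measured with the same staining protocol — MCF-7 (epithelial-like, low
vimentin) and MDA-MB-231 (mesenchymal-like, high vimentin).  PD-L1
positivity is anchored the same way on PD-L1 CTCF in the two lines.

The packaged default :class:`CalibrationModel` carries the published
reference ranges: vim/ker 0.01–0.28 (epithelial) and 0.88–22.5
(mesenchymal), PD-L1 CTCF 10–40 (negative/low) and 60–350 (positive).
A CTC with vim/ker ratio up to the mesenchymal lower bound (0.88) is
epithelial (eCTC); anything greater is mesenchymal (mCTC).  A CTC with
PD-L1 CTCF up to the epithelial upper bound (40) is negative/low; anything
greater is PD-L1 positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ReferenceDistribution",
    "CalibrationModel",
    "DEFAULT_CALIBRATION",
    "fit_reference_range",
    "build_calibration",
    "load_calibration",
    "save_calibration",
    "load_default_calibration",
]

#: Minimum number of reference cells required to fit a range.
MIN_REFERENCE_N = 100


@dataclass
class ReferenceDistribution:
    """Per-cell measurements of one reference cell line.

    Parameters
    ----------
    line_name:
        Name of the cell line (e.g. ``"MCF-7"``).
    vim_ker_ratios:
        Per-cell vimentin/keratin CTCF ratios; finite and strictly positive.
    pdl1_ctcf:
        Per-cell PD-L1 CTCF values (arbitrary fluorescence units).
    """

    line_name: str
    vim_ker_ratios: np.ndarray
    pdl1_ctcf: np.ndarray

    def __post_init__(self) -> None:
        self.vim_ker_ratios = np.asarray(self.vim_ker_ratios, dtype=float)
        self.pdl1_ctcf = np.asarray(self.pdl1_ctcf, dtype=float)
        if not np.all(np.isfinite(self.vim_ker_ratios)):
            raise ValueError(f"{self.line_name}: nonfinite vim/ker ratios")
        if np.any(self.vim_ker_ratios <= 0):
            raise ValueError(f"{self.line_name}: vim/ker ratios must be > 0")
        if not np.all(np.isfinite(self.pdl1_ctcf)):
            raise ValueError(f"{self.line_name}: nonfinite PD-L1 CTCF values")

    @property
    def n_cells(self) -> int:
        return int(self.vim_ker_ratios.size)


@dataclass(frozen=True)
class CalibrationModel:
    """Reference ranges and the derived classification thresholds.

    The EMT threshold equals the lower bound of the mesenchymal vim/ker
    range; the PD-L1 threshold equals the upper bound of the negative/low
    PD-L1 range.  Both are properties so they can never drift from the
    ranges they are defined by.
    """

    epithelial_ratio_range: tuple[float, float] = (0.01, 0.28)
    mesenchymal_ratio_range: tuple[float, float] = (0.88, 22.5)
    pdl1_negative_range: tuple[float, float] = (10.0, 40.0)
    pdl1_positive_range: tuple[float, float] = (60.0, 350.0)
    min_reference_n: int = MIN_REFERENCE_N
    provenance: str = "packaged defaults (MCF-7 / MDA-MB-231 reference ranges)"

    def __post_init__(self) -> None:
        for name in (
            "epithelial_ratio_range",
            "mesenchymal_ratio_range",
            "pdl1_negative_range",
            "pdl1_positive_range",
        ):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"{name}: bounds must be finite")
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper bound {hi}")

    @property
    def emt_ratio_threshold(self) -> float:
        """vim/ker ratio at and below which a CTC is epithelial."""
        return self.mesenchymal_ratio_range[0]

    @property
    def pdl1_threshold(self) -> float:
        """PD-L1 CTCF at and below which a CTC is negative/low."""
        return self.pdl1_negative_range[1]

    def to_dict(self) -> dict:
        return {
            "epithelial_ratio_range": [float(v) for v in self.epithelial_ratio_range],
            "mesenchymal_ratio_range": [float(v) for v in self.mesenchymal_ratio_range],
            "pdl1_negative_range": [float(v) for v in self.pdl1_negative_range],
            "pdl1_positive_range": [float(v) for v in self.pdl1_positive_range],
            "min_reference_n": int(self.min_reference_n),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        known = {
            "epithelial_ratio_range",
            "mesenchymal_ratio_range",
            "pdl1_negative_range",
            "pdl1_positive_range",
            "min_reference_n",
            "provenance",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown calibration keys: {sorted(unknown)}")
        kwargs = dict(d)
        for name in known - {"min_reference_n", "provenance"}:
            if name in kwargs:
                kwargs[name] = tuple(float(v) for v in kwargs[name])
        return cls(**kwargs)


#: The packaged default calibration carrying the published constants.
DEFAULT_CALIBRATION = CalibrationModel()


def fit_reference_range(
    values: Sequence[float] | np.ndarray,
    *,
    robust: bool = False,
    min_reference_n: int = MIN_REFERENCE_N,
) -> tuple[float, float]:
    """Fit a reference range [lo, hi] from per-cell measurements.

    Default mode returns the empirical ``[min, max]``; ``robust=True``
    returns the ``[1%, 99%]`` quantiles instead (outlier-resistant, but
    narrower than the published min/max convention).

    Raises
    ------
    ValueError
        If fewer than ``min_reference_n`` cells are supplied, or any value
        is nonfinite.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < min_reference_n:
        raise ValueError(
            f"reference range requires at least {min_reference_n} cells, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("reference values must be finite")
    if robust:
        lo, hi = np.quantile(arr, [0.01, 0.99])
    else:
        lo, hi = arr.min(), arr.max()
    return float(lo), float(hi)


def build_calibration(
    epithelial_ref: ReferenceDistribution,
    mesenchymal_ref: ReferenceDistribution,
    *,
    robust: bool = False,
    min_reference_n: int = MIN_REFERENCE_N,
) -> CalibrationModel:
    """Build a :class:`CalibrationModel` from two reference populations.

    ``epithelial_ref`` plays the MCF-7 role (defines the epithelial
    vim/ker range and the PD-L1 negative/low range), ``mesenchymal_ref``
    the MDA-MB-231 role.  Overlapping ranges are legal and warn: the
    published ranges themselves leave gaps (ratio 0.28–0.88, PD-L1 40–60),
    so gaps and overlaps are structural, not fatal.
    """
    kwargs = dict(robust=robust, min_reference_n=min_reference_n)
    epi_ratio = fit_reference_range(epithelial_ref.vim_ker_ratios, **kwargs)
    mes_ratio = fit_reference_range(mesenchymal_ref.vim_ker_ratios, **kwargs)
    pdl1_neg = fit_reference_range(epithelial_ref.pdl1_ctcf, **kwargs)
    pdl1_pos = fit_reference_range(mesenchymal_ref.pdl1_ctcf, **kwargs)

    if epi_ratio[1] >= mes_ratio[0]:
        warnings.warn(
            f"epithelial and mesenchymal vim/ker ranges overlap: "
            f"{epi_ratio} vs {mes_ratio}",
            stacklevel=2,
        )
    if pdl1_neg[1] >= pdl1_pos[0]:
        warnings.warn(
            f"PD-L1 negative and positive ranges overlap: {pdl1_neg} vs {pdl1_pos}",
            stacklevel=2,
        )
    mode = "quantile [1%,99%]" if robust else "empirical min/max"
    return CalibrationModel(
        epithelial_ratio_range=epi_ratio,
        mesenchymal_ratio_range=mes_ratio,
        pdl1_negative_range=pdl1_neg,
        pdl1_positive_range=pdl1_pos,
        min_reference_n=min_reference_n,
        provenance=(
            f"fitted ({mode}) from {epithelial_ref.line_name} "
            f"(n={epithelial_ref.n_cells}) and {mesenchymal_ref.line_name} "
            f"(n={mesenchymal_ref.n_cells})"
        ),
    )


def save_calibration(model: CalibrationModel, path: str | Path) -> None:
    """Write a calibration model to YAML (lossless round-trip)."""
    Path(path).write_text(yaml.safe_dump(model.to_dict(), sort_keys=True))


def load_calibration(path: str | Path) -> CalibrationModel:
    """Read a calibration model from YAML."""
    return CalibrationModel.from_dict(yaml.safe_load(Path(path).read_text()))


def load_default_calibration() -> CalibrationModel:
    """Load the packaged default calibration file."""
    from importlib import resources

    with resources.files("ctcpheno.data").joinpath("default_calibration.yaml").open() as fh:
        return CalibrationModel.from_dict(yaml.safe_load(fh))


def with_provenance(model: CalibrationModel, note: str) -> CalibrationModel:
    """Return a copy of ``model`` with an amended provenance note."""
    return replace(model, provenance=f"{model.provenance}; {note}")
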