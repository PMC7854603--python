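"""Dual-wavelength (280/495 nm) stoichiometry quantification.

SEC chromatograms and AUC sedimentation-coefficient distributions recorded
simultaneously at 280 nm (protein + some fluorophore bleed-through) and
495 nm (6FAM-labelled oligonucleotide only) allow independent quantification
of protein and oligonucleotide in each resolved species.  Peak areas are
integrated over species windows centred on the monomer/dimer/tetramer
markers, the 6FAM contribution to the 280-nm channel is unmixed with a
configurable crosstalk factor, and the oligo:protein molar ratio of each
species is reported in relative molar units (only ratios are meaningful —
absolute extinction/path-length calibration is out of scope).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "MultiwavelengthTrace",
    "SpeciesQuant",
    "integrate_peak",
    "calibrate_protein_extinction",
    "quantify_species",
    "assign_species",
    "DEFAULT_CROSSTALK_280",
]

#: default 280-nm signal contributed per unit of 495-nm 6FAM signal
#: (typical fluorescein absorbance spectrum; configurable)
DEFAULT_CROSSTALK_280 = 0.3

#: default species half-window widths
DEFAULT_HALF_WIDTH = {"sec": 0.75, "auc": 1.5}  # mL, Svedberg


@dataclass
class MultiwavelengthTrace:
    """Two-channel signal over retention volume (mL) or sedimentation (S)."""

    axis: np.ndarray
    a280: np.ndarray
    a495: np.ndarray
    axis_kind: str = "sec"
    markers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.a280 = np.asarray(self.a280, dtype=float)
        self.a495 = np.asarray(self.a495, dtype=float)
        if self.axis_kind not in ("sec", "auc"):
            raise ValueError("axis_kind must be 'sec' or 'auc'")
        if not (self.axis.shape == self.a280.shape == self.a495.shape):
            raise ValueError("axis and channels must have equal length")
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if not (np.all(np.isfinite(self.a280)) and np.all(np.isfinite(self.a495))):
            raise ValueError("channel signals must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"axis": self.axis, "a280": self.a280, "a495": self.a495})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, axis_kind="sec", markers=None) -> "MultiwavelengthTrace":
        df = pd.read_csv(path)
        return cls(
            axis=df["axis"].to_numpy(float),
            a280=df["a280"].to_numpy(float),
            a495=df["a495"].to_numpy(float),
            axis_kind=axis_kind,
            markers=markers or {},
        )


@dataclass
class SpeciesQuant:
    """Quantification of one species window."""

    species: str
    window: tuple
    area280: float
    area495: float
    mol_protein: float
    mol_oligo: float
    ratio: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _window_slice(trace: MultiwavelengthTrace, window) -> np.ndarray:
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError("window must satisfy lo < hi")
    if lo < trace.axis[0] - 1e-12 or hi > trace.axis[-1] + 1e-12:
        raise ValueError(
            f"window ({lo}, {hi}) outside axis range "
            f"({trace.axis[0]}, {trace.axis[-1]})"
        )
    mask = (trace.axis >= lo) & (trace.axis <= hi)
    if mask.sum() < 3:
        raise ValueError("window must contain at least 3 samples")
    return mask


def integrate_peak(
    trace: MultiwavelengthTrace, window, baseline: str = "linear-endpoints"
) -> tuple[float, float]:
    """Trapezoidal peak areas of both channels over a window.

    ``baseline='linear-endpoints'`` subtracts, per channel, the straight
    line anchored on the mean of a short segment at each end of the window
    (5 % of the window, at least 3 samples when available), which removes
    constant offsets and linear drifts exactly while staying robust to
    single-sample noise.  Areas driven negative by baseline subtraction are
    clipped at 0 with a warning.
    """
    if baseline not in ("none", "linear-endpoints"):
        raise ValueError("baseline must be 'none' or 'linear-endpoints'")
    mask = _window_slice(trace, window)
    x = trace.axis[mask]
    k = max(min(3, x.size // 2), int(round(0.05 * x.size)))
    areas = []
    for chan in (trace.a280[mask], trace.a495[mask]):
        y = chan.astype(float)
        if baseline == "linear-endpoints":
            x0, y0 = x[:k].mean(), y[:k].mean()
            x1, y1 = x[-k:].mean(), y[-k:].mean()
            slope = (y1 - y0) / (x1 - x0)
            y = y - (y0 + slope * (x - x0))
        area = float(np.trapezoid(y, x))
        if area < 0:
            warnings.warn(
                f"negative integrated area ({area:.3g}) clipped to 0; "
                "check the baseline window"
            )
            area = 0.0
        areas.append(area)
    return areas[0], areas[1]


def calibrate_protein_extinction(
    trace_protein_only: MultiwavelengthTrace,
    known_conc: float,
    window,
    baseline: str = "linear-endpoints",
    max_a495_fraction: float = 0.02,
) -> float:
    """Protein 280-nm response (area per µM) from a fluorophore-free run.

    The calibration trace must contain no 6FAM: a 495-nm area above
    ``max_a495_fraction`` of the 280-nm area raises a contamination error.
    """
    if known_conc <= 0:
        raise ValueError("known_conc must be > 0")
    area280, area495 = integrate_peak(trace_protein_only, window, baseline)
    if area280 <= 0:
        raise ValueError("no protein signal in the calibration window")
    if area495 > max_a495_fraction * area280:
        raise ValueError(
            "significant 495-nm signal in a protein-only calibration trace "
            f"(area495/area280 = {area495 / area280:.3g})"
        )
    return area280 / known_conc


def quantify_species(
    trace: MultiwavelengthTrace,
    window,
    eps280_protein: float,
    eps495_fam: float,
    fam_crosstalk_280: float = DEFAULT_CROSSTALK_280,
    species: str = "",
    baseline: str = "linear-endpoints",
) -> SpeciesQuant:
    """Oligo:protein molar ratio of one species by two-channel unmixing.

    The 495-nm channel sees only the 6FAM label: mol_oligo = area495 /
    eps495_fam.  6FAM also absorbs at 280 nm; its contribution there is
    ``fam_crosstalk_280 * area495`` and is subtracted before converting to
    protein moles:  mol_protein = (area280 - crosstalk * area495) /
    eps280_protein.  A non-positive corrected protein area raises an
    unmixing error.
    """
    if eps280_protein <= 0 or eps495_fam <= 0:
        raise ValueError("extinction scales must be > 0")
    if not 0.0 <= fam_crosstalk_280 < 1.0:
        raise ValueError("fam_crosstalk_280 must lie in [0, 1)")
    area280, area495 = integrate_peak(trace, window, baseline)
    mol_oligo = area495 / eps495_fam
    corrected280 = area280 - fam_crosstalk_280 * area495
    if corrected280 <= 0:
        raise ValueError(
            "corrected protein area <= 0 after 6FAM crosstalk subtraction; "
            "unmixing failed"
        )
    mol_protein = corrected280 / eps280_protein
    return SpeciesQuant(
        species=species,
        window=(float(window[0]), float(window[1])),
        area280=area280,
        area495=area495,
        mol_protein=mol_protein,
        mol_oligo=mol_oligo,
        ratio=mol_oligo / mol_protein,
    )


def assign_species(
    trace: MultiwavelengthTrace,
    markers: dict | None = None,
    half_width: float | None = None,
) -> dict:
    """Build one integration window per species marker.

    Windows are centred on the marker positions (monomer/dimer/tetramer
    retention volumes, or S-values), clipped to the axis range, and truncated
    at the midpoint between adjacent markers when they would overlap (with a
    warning).  Returns ``{species: (lo, hi)}``.
    """
    markers = markers if markers is not None else trace.markers
    if not markers:
        raise ValueError("no species markers given")
    vals = list(markers.values())
    if len(set(vals)) != len(vals):
        raise ValueError("species markers must be distinct")
    if half_width is None:
        half_width = DEFAULT_HALF_WIDTH[trace.axis_kind]
    order = sorted(markers.items(), key=lambda kv: kv[1])
    lo_ax, hi_ax = float(trace.axis[0]), float(trace.axis[-1])
    windows = {}
    for i, (name, centre) in enumerate(order):
        lo = centre - half_width
        hi = centre + half_width
        if i > 0:
            mid = 0.5 * (order[i - 1][1] + centre)
            if lo < mid:
                warnings.warn(
                    f"windows of {order[i - 1][0]} and {name} overlap; "
                    "truncated at their midpoint"
                )
                lo = mid
        if i + 1 < len(order):
            mid = 0.5 * (centre + order[i + 1][1])
            hi = min(hi, mid)
        windows[name] = (max(lo, lo_ax), min(hi, hi_ax))
    return windows
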