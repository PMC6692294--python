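"""Residue-resolved sPRE profiles: prediction, normalization, deviation flagging.

A full-sequence random-coil prediction is assembled by sliding a 5-residue
window over the sequence and looking up (or computing) the fragment-library
record of each window; the central residue inherits the ensemble mean and
SD.  Predicted profiles are in arbitrary grid units and are mapped onto the
experimental scale (s^-1 mM^-1) by an ordinary least-squares shift/scale.
Residues whose measured sPRE deviates from the normalized coil prediction
beyond a z-threshold, in runs of a minimum length, are flagged as buried
(transient structure or long-range contacts) or exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coil_ensemble import DEFAULT_CONFIG, CoilSamplerConfig, FragmentLibrary
from .grid_spre import GridParams
from .structure_model import ONE_TO_THREE

__all__ = [
    "SPREProfile",
    "NormalizationResult",
    "DeviationReport",
    "enumerate_windows",
    "predict_profile",
    "normalize_prediction",
    "compare_and_flag",
    "bulkiness_profile",
    "ZIMMERMAN_BULKINESS",
]

#: Zimmerman side-chain bulkiness scale
ZIMMERMAN_BULKINESS = {
    "A": 11.50, "R": 14.28, "N": 12.82, "D": 11.68, "C": 13.46,
    "Q": 14.45, "E": 13.57, "G": 3.40, "H": 13.69, "I": 21.40,
    "L": 21.40, "K": 15.71, "M": 16.25, "F": 19.80, "P": 17.43,
    "S": 9.47, "T": 15.77, "W": 21.67, "Y": 18.03, "V": 21.57,
}

_PROFILE_COLUMNS = ["residue_index", "role", "value", "error"]


@dataclass
class SPREProfile:
    """Per-residue, per-role sPRE values with errors.

    ``data`` has columns residue_index, role, value, error; a residue/role
    combination is *defined* iff a row exists.  Values are in arbitrary
    units for predictions and s^-1 mM^-1 for experimental profiles.
    """

    sequence: str
    data: pd.DataFrame

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)[_PROFILE_COLUMNS].copy()
        L = len(self.sequence)
        idx = self.data["residue_index"]
        if len(idx) and (idx.min() < 1 or idx.max() > L):
            raise ValueError("residue indices outside 1..L")
        if (self.data["error"].dropna() < 0).any():
            raise ValueError("errors must be >= 0")

    def role_series(self, role: str) -> pd.DataFrame:
        """Rows of one role, indexed by residue_index (value, error)."""
        sub = self.data[self.data["role"] == role]
        return sub.set_index("residue_index")[["value", "error"]].sort_index()

    def defined_residues(self, role: str) -> np.ndarray:
        return np.sort(self.data.loc[self.data["role"] == role, "residue_index"].unique())

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(1, "residue_name", [
            ONE_TO_THREE[self.sequence[i - 1]] for i in out["residue_index"]
        ])
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sequence: str) -> "SPREProfile":
        df = pd.read_csv(path, sep="\t")
        missing = set(_PROFILE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"profile table missing column(s) {sorted(missing)}")
        return cls(sequence=sequence, data=df[_PROFILE_COLUMNS])


def enumerate_windows(sequence: str) -> list[tuple[int, str]]:
    """All 5-mer windows of a sequence as (center_index, core) pairs.

    Centers run from residue 3 to L-2 (1-based); the first/last two
    residues of the chain are never window centers and therefore carry no
    prediction.
    """
    sequence = sequence.upper()
    if len(sequence) < 5:
        raise ValueError("sequence must have at least 5 residues")
    bad = [c for c in sequence if c not in ONE_TO_THREE]
    if bad:
        raise ValueError(f"noncanonical residue letter(s) {bad}")
    return [
        (center, sequence[center - 3:center + 2])
        for center in range(3, len(sequence) - 1)
    ]


def predict_profile(
    sequence: str,
    library: FragmentLibrary | None = None,
    n: int = 1500,
    seed: int = 0,
    grid_params: GridParams | None = None,
    roles: tuple[str, ...] = ("HA", "CA"),
    config: CoilSamplerConfig = DEFAULT_CONFIG,
) -> SPREProfile:
    """Predict the random-coil sPRE profile of a sequence.

    Residue i (3 <= i <= L-2) receives the ensemble mean of the central
    residue of its 5-mer window, with the ensemble SD as error.  Window
    records missing from the library are computed on demand and cached.
    """
    library = library if library is not None else FragmentLibrary()
    grid_params = grid_params or GridParams()
    rows = []
    for center, core in enumerate_windows(sequence):
        rec = library.get_or_compute(core, n, seed, grid_params, roles, config)
        for role in roles:
            s = rec.stats[role]
            rows.append({
                "residue_index": center, "role": role,
                "value": s["mean"], "error": s["sd"],
            })
    return SPREProfile(sequence=sequence.upper(), data=pd.DataFrame(rows))


@dataclass
class NormalizationResult:
    """Linear map of a predicted profile onto the experimental scale."""

    slope: float
    intercept: float
    role: str
    normalized: SPREProfile
    residuals: pd.Series  # experimental - normalized, over co-defined residues
    n_used: int
    trimmed: list = field(default_factory=list)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0:
        raise ValueError("predicted values are constant; normalization fit is degenerate")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def normalize_prediction(
    predicted: SPREProfile,
    experimental: SPREProfile,
    role: str,
    robust: bool = False,
    trim_sigma: float = 2.5,
    max_iter: int = 5,
) -> NormalizationResult:
    """Shift/scale a predicted profile onto an experimental one.

    Fits experimental = slope * predicted + intercept by OLS over residues
    where both are defined, then applies the map to the whole predicted
    profile (errors scaled by |slope|).  With ``robust=True`` the fit
    iteratively drops points whose |residual| exceeds ``trim_sigma`` robust
    scale units (1.4826 * MAD, so outliers cannot inflate their own
    rejection threshold) and refits — useful because genuinely structured regions bias the
    plain fit, at the price of departing from a plain shift/scale.
    """
    if predicted.sequence != experimental.sequence:
        raise ValueError("profiles describe different sequences")
    pred = predicted.role_series(role)
    exp = experimental.role_series(role)
    common = pred.index.intersection(exp.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 co-defined residues for role {role!r}, have {len(common)}")
    x = pred.loc[common, "value"].to_numpy(float)
    y = exp.loc[common, "value"].to_numpy(float)
    slope, intercept = _ols(x, y)
    trimmed: list[int] = []
    if robust:
        keep = np.ones(len(common), bool)
        for _ in range(max_iter):
            resid = y - (slope * x + intercept)
            scale = 1.4826 * np.median(np.abs(resid[keep] - np.median(resid[keep])))
            if scale == 0:
                break
            new_keep = keep & (np.abs(resid) <= trim_sigma * scale)
            if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
                break
            keep = new_keep
            slope, intercept = _ols(x[keep], y[keep])
        trimmed = [int(r) for r in np.asarray(common)[~keep]]
    norm_data = predicted.data.copy()
    sel = norm_data["role"] == role
    norm_data.loc[sel, "value"] = slope * norm_data.loc[sel, "value"] + intercept
    norm_data.loc[sel, "error"] = abs(slope) * norm_data.loc[sel, "error"]
    normalized = SPREProfile(sequence=predicted.sequence, data=norm_data)
    residuals = pd.Series(
        y - (slope * x + intercept), index=common, name="residual"
    )
    return NormalizationResult(
        slope=slope, intercept=intercept, role=role, normalized=normalized,
        residuals=residuals, n_used=len(common), trimmed=trimmed,
    )


@dataclass
class DeviationReport:
    """Residues where measurement and coil prediction disagree.

    ``deviations`` holds (normalized predicted - experimental) / error per
    co-defined residue; positive means the residue is less solvent-exposed
    than a random coil ("buried").  ``regions`` are maximal runs of at
    least ``min_run`` consecutively flagged residues of one direction.
    """

    role: str
    deviations: pd.Series
    regions: list[tuple[int, int, str]]
    z_threshold: float
    min_run: int
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "role": self.role,
            "z_threshold": self.z_threshold,
            "min_run": self.min_run,
            "deviations": {int(k): float(v) for k, v in self.deviations.items()},
            "regions": [
                {"start": s, "end": e, "direction": d} for s, e, d in self.regions
            ],
            "notes": self.notes,
        }


def _runs(flags: pd.Series, min_run: int) -> list[tuple[int, int, str]]:
    """Maximal runs of >= min_run consecutive residues with one flag value."""
    regions = []
    start = prev = None
    current = None
    for idx, val in flags.items():
        contiguous = prev is not None and idx == prev + 1 and val == current
        if val is not None and contiguous:
            prev = idx
        else:
            if current is not None and prev - start + 1 >= min_run:
                regions.append((start, prev, current))
            start, prev, current = (idx, idx, val) if val is not None else (None, None, None)
    if current is not None and prev - start + 1 >= min_run:
        regions.append((start, prev, current))
    return regions


def compare_and_flag(
    normalized: SPREProfile,
    experimental: SPREProfile,
    role: str,
    z_threshold: float = 1.96,
    min_run: int = 3,
) -> DeviationReport:
    """Flag residues whose measured sPRE deviates from the coil prediction.

    A residue is "buried" when the normalized prediction exceeds the
    measurement by more than ``z_threshold`` experimental errors (the coil
    overestimates its accessibility), "exposed" for the opposite sign.
    Only runs of at least ``min_run`` consecutive same-direction flags
    become regions.  Amide-proton (HN) comparisons carry a caveat: solvent
    exchange can inflate experimental amide sPREs.
    """
    if normalized.sequence != experimental.sequence:
        raise ValueError("profiles describe different sequences")
    pred = normalized.role_series(role)
    exp = experimental.role_series(role)
    common = pred.index.intersection(exp.index)
    err = exp.loc[common, "error"].to_numpy(float)
    if np.all(err == 0):
        raise ValueError("all experimental errors are zero; z-scores undefined")
    if np.any(err <= 0):
        raise ValueError("experimental errors must be > 0 where defined")
    diff = pred.loc[common, "value"].to_numpy(float) - exp.loc[common, "value"].to_numpy(float)
    z = pd.Series(diff / err, index=common, name="z")
    flags = pd.Series(
        [("buried" if v > z_threshold else "exposed" if v < -z_threshold else None) for v in z],
        index=common, dtype=object,
    )
    notes = []
    if role == "HN":
        notes.append(
            "HN comparison is exchange-confounded: amide-proton exchange with "
            "fast-relaxing water protons can raise the experimental sPRE."
        )
    return DeviationReport(
        role=role, deviations=z, regions=_runs(flags, min_run),
        z_threshold=z_threshold, min_run=min_run, notes=notes,
    )


def bulkiness_profile(sequence: str, window: int = 1) -> np.ndarray:
    """Zimmerman bulkiness per residue, sliding-window averaged.

    A crude sequence-only accessibility baseline: bulky residues (V, I, L,
    W) exclude more solvent than glycine.  Edge residues use truncated
    windows.  ``window`` must be odd.
    """
    sequence = sequence.upper()
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    try:
        raw = np.array([ZIMMERMAN_BULKINESS[c] for c in sequence])
    except KeyError as e:
        raise ValueError(f"noncanonical residue letter {e.args[0]!r}") from None
    half = window // 2
    return np.array([
        raw[max(0, i - half):i + half + 1].mean() for i in range(len(raw))
    ])
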