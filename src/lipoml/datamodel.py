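"""Core domain types for microfluidic liposome measurement libraries.

A *formulation* is one combination of the four engineering parameters of the
microfluidic synthesis: total flow rate (TFR, ml/min), total lipid
concentration (mg/ml), aqueous:organic volume ratio (V_a/V_o) and the
presence/absence of curcumin as a model drug.  A *measurement* is one dynamic
light scattering (DLS) observation of a formulation replicate on a given day:
hydrodynamic diameter (nm), polydispersity index (PdI) and, optionally, the
surface zeta-potential (mV).

This module holds the measurement-library container (a thin wrapper over a
pandas DataFrame), CSV I/O, replicate capping, and the dispersity/stability
labeling rules every downstream model consumes:

* binary dispersity: monodisperse iff PdI <= 0.220 (threshold inclusive);
* multiclass dispersity: "PdI <= 0.200", "PdI <= 0.300", "polydisperse";
* stability: a formulation is stable if a one-sided one-sample t-test cannot
  show that its mean PdI over the observation window exceeds 0.220
  (p >= 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BINARY_PDI_THRESHOLD",
    "MULTICLASS_BOUNDS",
    "CANONICAL_COLUMNS",
    "SynthesisParams",
    "Measurement",
    "MeasurementLibrary",
    "DispersityLabel",
    "StabilityLabel",
    "SchemaError",
    "ParseError",
    "InsufficientDataError",
    "read_library",
    "write_library",
    "cap_replicates",
    "label_dispersity",
    "label_stability",
    "label_all_stability",
]

#: Monodisperse/polydisperse PdI threshold (inclusive on the monodisperse side).
BINARY_PDI_THRESHOLD = 0.220
#: Multiclass dispersity boundaries (both inclusive).
MULTICLASS_BOUNDS = (0.200, 0.300)

#: Canonical CSV column names (the package's interchange dialect).
CANONICAL_COLUMNS = (
    "tfr_ml_min",
    "lipid_mg_ml",
    "va_vo",
    "curcumin",
    "day",
    "replicate",
    "diameter_nm",
    "pdi",
    "zeta_mv",
)

PARAM_COLUMNS = ("tfr_ml_min", "lipid_mg_ml", "va_vo", "curcumin")

Scheme = Literal["binary", "multiclass"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ParseError(ValueError):
    """A cell could not be parsed as the expected numeric type."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


@dataclass(frozen=True, order=True)
class SynthesisParams:
    """The four engineering inputs of one microfluidic run.

    Equality of two instances defines "unique formulation" membership.
    """

    tfr: float  # total flow rate, ml/min
    lipid_conc: float  # total lipid concentration, mg/ml
    va_vo: float  # aqueous:organic volume ratio
    curcumin: bool  # model drug present?

    def __post_init__(self) -> None:
        if not (self.tfr > 0 and self.lipid_conc > 0 and self.va_vo > 0):
            raise ValueError(
                f"synthesis parameters must be positive, got "
                f"tfr={self.tfr}, lipid_conc={self.lipid_conc}, va_vo={self.va_vo}"
            )

    def as_tuple(self) -> tuple[float, float, float, int]:
        return (float(self.tfr), float(self.lipid_conc), float(self.va_vo), int(self.curcumin))


@dataclass(frozen=True)
class Measurement:
    """One DLS observation of a formulation replicate on a given day."""

    params: SynthesisParams
    day: int
    replicate_id: int
    diameter: float  # hydrodynamic diameter, nm
    pdi: float
    zeta: float | None = None  # zeta-potential, mV

    def __post_init__(self) -> None:
        if self.day not in (0, 1, 2, 3):
            raise ValueError(f"day must be in 0..3, got {self.day}")
        if self.replicate_id < 1:
            raise ValueError(f"replicate_id must be >= 1, got {self.replicate_id}")
        if not self.diameter > 0:
            raise ValueError(f"diameter must be positive, got {self.diameter}")
        if self.pdi < 0:
            raise ValueError(f"pdi must be non-negative, got {self.pdi}")


class MeasurementLibrary:
    """An ordered collection of measurements with formulation grouping.

    Backed by a pandas DataFrame in the canonical column dialect; the frame is
    validated on construction (positivity, day range, key uniqueness).
    """

    def __init__(self, frame: pd.DataFrame, provenance: str = "") -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns and c != "zeta_mv"]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        frame = frame.copy()
        if "zeta_mv" not in frame.columns:
            frame["zeta_mv"] = np.nan
        frame = frame.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)
        for col in ("tfr_ml_min", "lipid_mg_ml", "va_vo", "diameter_nm", "pdi", "zeta_mv"):
            frame[col] = frame[col].astype(float)
        for col in ("curcumin", "day", "replicate"):
            frame[col] = frame[col].astype(int)
        if len(frame):
            if (frame["diameter_nm"] <= 0).any():
                raise ValueError("all diameters must be positive")
            if (frame["pdi"] < 0).any():
                raise ValueError("all PdI values must be non-negative")
            if ~frame["day"].isin([0, 1, 2, 3]).all():
                raise ValueError("day must be in 0..3")
            dup = frame.duplicated(subset=[*PARAM_COLUMNS, "replicate", "day"])
            if dup.any():
                raise ValueError(
                    f"duplicate (params, replicate, day) keys at rows {list(frame.index[dup])}"
                )
        self.frame = frame
        self.provenance = provenance

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementLibrary):
            return NotImplemented
        return self.frame.equals(other.frame)

    @property
    def n_formulations(self) -> int:
        """Number of distinct synthesis-parameter combinations."""
        return len(self.frame.drop_duplicates(subset=list(PARAM_COLUMNS)))

    def formulations(self) -> list[SynthesisParams]:
        uniq = self.frame.drop_duplicates(subset=list(PARAM_COLUMNS))
        return [
            SynthesisParams(r.tfr_ml_min, r.lipid_mg_ml, r.va_vo, bool(r.curcumin))
            for r in uniq.itertuples()
        ]

    def measurements(self) -> Iterable[Measurement]:
        for r in self.frame.itertuples():
            yield Measurement(
                SynthesisParams(r.tfr_ml_min, r.lipid_mg_ml, r.va_vo, bool(r.curcumin)),
                int(r.day),
                int(r.replicate),
                float(r.diameter_nm),
                float(r.pdi),
                None if pd.isna(r.zeta_mv) else float(r.zeta_mv),
            )

    def subset(self, mask: pd.Series, provenance_suffix: str = "") -> "MeasurementLibrary":
        return MeasurementLibrary(self.frame.loc[mask], self.provenance + provenance_suffix)

    def day0(self) -> "MeasurementLibrary":
        """Measurements made directly after synthesis."""
        return self.subset(self.frame["day"] == 0, "|day0")

    def select(self, params: SynthesisParams) -> pd.DataFrame:
        f = self.frame
        mask = (
            (f["tfr_ml_min"] == params.tfr)
            & (f["lipid_mg_ml"] == params.lipid_conc)
            & (f["va_vo"] == params.va_vo)
            & (f["curcumin"] == int(params.curcumin))
        )
        return f.loc[mask]

    def groupby_formulation(self):
        return self.frame.groupby(list(PARAM_COLUMNS), sort=True)


@dataclass(frozen=True)
class DispersityLabel:
    scheme: Scheme
    label: str


@dataclass(frozen=True)
class StabilityLabel:
    stable: bool
    p_value: float
    mean_pdi: float
    n_obs: int


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_NUMERIC_COLUMNS = ("tfr_ml_min", "lipid_mg_ml", "va_vo", "day", "replicate", "diameter_nm", "pdi", "zeta_mv")


def read_library(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> MeasurementLibrary:
    """Read a measurement library from CSV.

    Parameters
    ----------
    path
        CSV file with one row per DLS measurement.
    dialect
        Optional map from canonical column names to the file's column names,
        for tables exported with different headers.  Unmapped names are
        assumed canonical.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str)
    dialect = dict(dialect or {})
    rename = {dialect.get(c, c): c for c in CANONICAL_COLUMNS}
    raw = raw.rename(columns=rename)

    required = [c for c in CANONICAL_COLUMNS if c != "zeta_mv"]
    for col in required:
        if col not in raw.columns:
            raise SchemaError(f"missing required column: {col!r}")

    frame = pd.DataFrame(index=raw.index)
    for col in _NUMERIC_COLUMNS:
        if col not in raw.columns:
            continue
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            row = int(raw.index[bad][0])
            raise ParseError(f"non-numeric value in column {col!r} at row {row}: {raw[col][row]!r}")
        # astype(float) uses python's exact (shortest-round-trip) parser;
        # to_numeric above only validates
        frame[col] = raw[col].where(raw[col].notna(), None).astype(float)
    if frame[["tfr_ml_min", "lipid_mg_ml", "va_vo", "day", "replicate", "diameter_nm", "pdi"]].isna().any().any():
        col = frame.columns[frame.isna().any()][0]
        row = int(frame.index[frame[col].isna()][0])
        raise ParseError(f"empty value in column {col!r} at row {row}")
    frame["curcumin"] = pd.to_numeric(raw["curcumin"], errors="coerce").astype(int)
    frame["day"] = frame["day"].astype(int)
    frame["replicate"] = frame["replicate"].astype(int)
    return MeasurementLibrary(frame, provenance if provenance is not None else str(path))


def write_library(lib: MeasurementLibrary, path: str | Path) -> None:
    """Write a library to CSV in the canonical dialect (lossless round-trip)."""
    # no float_format: pandas' default str() is shortest-round-trip in py3,
    # so written values parse back bit-identically
    frame = lib.frame.copy()
    frame["curcumin"] = frame["curcumin"].astype(int)
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Replicate capping
# ---------------------------------------------------------------------------


def cap_replicates(lib: MeasurementLibrary, max_n: int, seed: int) -> MeasurementLibrary:
    """Restrict each formulation to at most ``max_n`` replicates.

    If a formulation has more than ``max_n`` distinct replicate ids, a uniform
    random subset of ``max_n`` ids is retained; all days of a retained
    replicate are kept together.  Reproducible under ``seed``.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(lib.frame), dtype=bool)
    frame = lib.frame
    for _, idx in frame.groupby(list(PARAM_COLUMNS), sort=True).indices.items():
        reps = np.unique(frame["replicate"].to_numpy()[idx])
        if len(reps) > max_n:
            reps = rng.choice(reps, size=max_n, replace=False)
        keep[idx] = np.isin(frame["replicate"].to_numpy()[idx], reps)
    return MeasurementLibrary(frame.loc[keep], lib.provenance + f"|cap{max_n}")


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------


def label_dispersity(measurement: Measurement | float, scheme: Scheme = "binary") -> DispersityLabel:
    """Label a PdI (or a measurement) under the binary or multiclass scheme.

    Binary: monodisperse iff PdI <= 0.220.  Multiclass: first match of
    PdI <= 0.200, PdI <= 0.300, else polydisperse.  All thresholds inclusive.
    """
    pdi = measurement.pdi if isinstance(measurement, Measurement) else float(measurement)
    if pdi < 0:
        raise ValueError(f"pdi must be non-negative, got {pdi}")
    if scheme == "binary":
        label = "monodisperse" if pdi <= BINARY_PDI_THRESHOLD else "polydisperse"
    elif scheme == "multiclass":
        lo, hi = MULTICLASS_BOUNDS
        if pdi <= lo:
            label = "PdI <= 0.200"
        elif pdi <= hi:
            label = "PdI <= 0.300"
        else:
            label = "polydisperse"
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return DispersityLabel(scheme=scheme, label=label)


def stability_t_test(pdi_values: Sequence[float], threshold: float = BINARY_PDI_THRESHOLD) -> tuple[float, float]:
    """One-sample, one-sided t-test with H1: mean PdI > threshold.

    Returns ``(t, p)``.  Zero-variance vectors are resolved as the limit of
    the test: p = 1 if the mean does not exceed the threshold, else p = 0.
    """
    x = np.asarray(pdi_values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"need >= 2 PdI observations, got {x.size}")
    s = x.std(ddof=1)
    mean = x.mean()
    if s == 0.0:
        return (np.inf if mean > threshold else -np.inf, 0.0 if mean > threshold else 1.0)
    t, p = stats.ttest_1samp(x, popmean=threshold, alternative="greater")
    return float(t), float(p)


def label_stability(
    lib: MeasurementLibrary,
    params: SynthesisParams,
    threshold: float = BINARY_PDI_THRESHOLD,
    alpha: float = 0.05,
    days: Sequence[int] = (0, 1, 2, 3),
    per_day_mean: bool = False,
) -> StabilityLabel:
    """Stability of one formulation over the observation window.

    The formulation's PdI observations over ``days`` are pooled (or first
    averaged per day when ``per_day_mean``) and a one-sided one-sample t-test
    asks whether the mean PdI is greater than ``threshold``.  The formulation
    is stable iff p >= ``alpha``.
    """
    rows = lib.select(params)
    rows = rows[rows["day"].isin(list(days))]
    if per_day_mean:
        x = rows.groupby("day")["pdi"].mean().to_numpy()
    else:
        x = rows["pdi"].to_numpy()
    t, p = stability_t_test(x, threshold)
    return StabilityLabel(stable=bool(p >= alpha), p_value=p, mean_pdi=float(np.mean(x)), n_obs=int(x.size))


def label_all_stability(
    lib: MeasurementLibrary,
    threshold: float = BINARY_PDI_THRESHOLD,
    alpha: float = 0.05,
    days: Sequence[int] = (0, 1, 2, 3),
    per_day_mean: bool = False,
) -> pd.DataFrame:
    """Stability labels for every formulation; one row per formulation."""
    records = []
    for key, grp in lib.groupby_formulation():
        grp = grp[grp["day"].isin(list(days))]
        x = grp.groupby("day")["pdi"].mean().to_numpy() if per_day_mean else grp["pdi"].to_numpy()
        t, p = stability_t_test(x, threshold)
        records.append(
            {
                "tfr_ml_min": key[0],
                "lipid_mg_ml": key[1],
                "va_vo": key[2],
                "curcumin": int(key[3]),
                "stable": bool(p >= alpha),
                "p_value": p,
                "mean_pdi": float(np.mean(x)),
                "n_obs": int(x.size),
            }
        )
    return pd.DataFrame.from_records(records)
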