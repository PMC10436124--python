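"""Cohort containers, counting-process expansion, and exposure quantization.

The analysis operates on person-period ("start-stop") records: each subject
contributes one row per calendar year of follow-up, carrying that year's
annual-mean exposures (PM2.5, MDA8 ozone, temperature) and the subject's
baseline covariates.  Intervals are half-open ``(start, stop]`` on the
time-on-study scale (years since cohort entry); a subject is at risk at time
``t`` if ``start < t <= stop``.  At most one record per subject carries
``event = 1`` and it is the subject's last.

Exposures enter the hazard models as quartile scores 0-3.  The quantization
rule is right-closed: ``x <= q25 -> 0``, ``q25 < x <= q50 -> 1``,
``q50 < x <= q75 -> 2``, ``x > q75 -> 3``; ties at a cut point fall in the
lower category.  Empirical cut points are the 25/50/75th percentiles of the
exposure over all person-period records, using linear interpolation between
order statistics (numpy's default, R type 7).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PersonPeriod",
    "Cohort",
    "QuantileSpec",
    "CohortError",
    "SchemaError",
    "ValidationError",
    "DegenerateQuantileError",
    "read_cohort",
    "write_cohort",
    "expand_counting_process",
    "empirical_cuts",
    "quantize",
    "design_matrix",
]

ID_COLUMNS = ["subject_id", "start", "stop", "event"]


class CohortError(Exception):
    """Base class for cohort construction and validation failures."""


class SchemaError(CohortError):
    """A required column is missing or a category label is not in the schema."""


class ValidationError(CohortError):
    """A record violates the person-period invariants."""


class DegenerateQuantileError(CohortError):
    """Exposure distribution too degenerate to define quartile categories."""


@dataclass(frozen=True)
class PersonPeriod:
    """One subject-interval row in counting-process form.

    Attributes
    ----------
    subject_id : str
        Opaque subject identifier.
    start, stop : float
        Interval bounds in years of time-on-study; ``start < stop`` and the
        interval is half-open ``(start, stop]``.
    event : int
        1 if the first asthmatic-symptom onset occurs at ``stop``.
    exposures : mapping
        Exposure name -> annual-mean value for this interval's calendar year.
    covariates : mapping
        Covariate name -> category label (time-constant within subject).
    """

    subject_id: str
    start: float
    stop: float
    event: int
    exposures: Mapping[str, float] = field(default_factory=dict)
    covariates: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class QuantileSpec:
    """Per-exposure quartile cut points mapping a continuous value to 0-3.

    ``cut_points`` holds (q25, q50, q75), strictly increasing.  ``source`` is
    ``"empirical"`` when derived from the data being quantized, ``"fixed"``
    when supplied externally.
    """

    exposure: str
    cut_points: tuple[float, float, float]
    source: str = "empirical"

    def __post_init__(self) -> None:
        c = np.asarray(self.cut_points, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise DegenerateQuantileError(
                f"{self.exposure}: need 3 finite cut points, got {self.cut_points!r}"
            )
        if not (c[0] < c[1] < c[2]):
            raise DegenerateQuantileError(
                f"{self.exposure}: cut points must be strictly increasing, got {tuple(c)}"
            )

    def apply(self, values: np.ndarray | pd.Series) -> np.ndarray:
        """Map values to categories 0-3 with right-closed bins (ties go down)."""
        x = np.asarray(values, dtype=float)
        # side="left": count of cut points strictly below x, which for strictly
        # increasing cuts is exactly the right-closed-bin category.
        return np.searchsorted(np.asarray(self.cut_points), x, side="left").astype(np.int64)

    def to_json(self) -> str:
        return json.dumps(
            {"exposure": self.exposure, "cuts": list(self.cut_points), "source": self.source}
        )

    @classmethod
    def from_json(cls, text: str) -> "QuantileSpec":
        d = json.loads(text)
        return cls(d["exposure"], tuple(d["cuts"]), d.get("source", "fixed"))


@dataclass
class Cohort:
    """A collection of person-period records plus its exposure/covariate schema.

    Parameters
    ----------
    data : DataFrame
        Columns ``subject_id, start, stop, event`` plus one numeric column per
        exposure and one string column per covariate.  Row order within a
        subject is interval order.
    exposure_names : list of str
        Ordered exposure columns.
    covariate_schema : dict
        Covariate name -> ordered category labels; the first label is the
        reference level for design matrices.
    """

    data: pd.DataFrame
    exposure_names: list[str]
    covariate_schema: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        df = self.data
        for col in ID_COLUMNS + list(self.exposure_names) + list(self.covariate_schema):
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        bad = np.flatnonzero(~(df["start"].to_numpy() < df["stop"].to_numpy()))
        if bad.size:
            raise ValidationError(f"start >= stop at row {int(bad[0])}")
        ev = df["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            bad = int(np.flatnonzero(~np.isin(ev, (0, 1)))[0])
            raise ValidationError(f"event not in {{0,1}} at row {bad}")
        for col in self.exposure_names:
            vals = df[col].to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                bad = int(np.flatnonzero(~np.isfinite(vals))[0])
                raise ValidationError(f"non-finite {col!r} at row {bad}")
        for cov, levels in self.covariate_schema.items():
            unknown = set(df[cov].astype(str)) - set(levels)
            if unknown:
                raise SchemaError(f"covariate {cov!r} has labels outside schema: {sorted(unknown)}")
        # within-subject interval ordering; event only on the last record.
        # Subjects are contiguous row blocks (construction and CSV contract),
        # so consecutive-row comparisons cover all within-subject pairs.
        sid = df["subject_id"].to_numpy()
        same = sid[1:] == sid[:-1]
        if (np.count_nonzero(~same) + 1) != len(set(sid)):
            raise ValidationError("subject records must form contiguous row blocks")
        start_a, stop_a = df["start"].to_numpy(float), df["stop"].to_numpy(float)
        bad = same & (start_a[1:] < stop_a[:-1] - 1e-12)
        if bad.any():
            who = sid[1:][bad][0]
            raise ValidationError(f"subject {who!r}: overlapping or unordered intervals")
        bad = same & (ev[:-1] == 1)
        if bad.any():
            who = sid[:-1][bad][0]
            raise ValidationError(f"subject {who!r}: event on a non-terminal record")
        counts = pd.Series(ev).groupby(pd.Series(sid)).sum()
        if (counts > 1).any():
            raise ValidationError("a subject has more than one event record")

    # -- summaries ----------------------------------------------------------

    @property
    def person_years(self) -> float:
        return float((self.data["stop"] - self.data["start"]).sum())

    @property
    def n_subjects(self) -> int:
        return int(self.data["subject_id"].nunique())

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def records(self) -> Iterator[PersonPeriod]:
        cov_cols = list(self.covariate_schema)
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            yield PersonPeriod(
                subject_id=str(d["subject_id"]),
                start=float(d["start"]),
                stop=float(d["stop"]),
                event=int(d["event"]),
                exposures={e: float(d[e]) for e in self.exposure_names},
                covariates={c: str(d[c]) for c in cov_cols},
            )

    def subset(self, mask: np.ndarray) -> "Cohort":
        """Row-subset (e.g. a covariate stratum) sharing the same schema."""
        return Cohort(
            self.data.loc[mask].reset_index(drop=True).copy(),
            list(self.exposure_names),
            dict(self.covariate_schema),
        )


# ---------------------------------------------------------------------------
# I/O


def read_cohort(
    path,
    covariate_schema: Mapping[str, Sequence[str]],
    exposure_names: Sequence[str] = ("pm25", "o3", "temp"),
) -> Cohort:
    """Read a person-period CSV (UTF-8, header row) into a validated Cohort.

    Required columns: ``subject_id,start,stop,event``, one per exposure and one
    per covariate in the schema.  Extra columns are preserved.
    """
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    for col in ID_COLUMNS + list(exposure_names) + list(covariate_schema):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    df["event"] = df["event"].astype(int)
    return Cohort(df, list(exposure_names), {k: list(v) for k, v in covariate_schema.items()})


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort to CSV with full float precision (round-trip safe)."""
    cohort.data.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# counting-process expansion


def expand_counting_process(
    subjects: pd.DataFrame,
    annual_exposures: pd.DataFrame,
    followup: pd.DataFrame,
    exposure_names: Sequence[str] = ("pm25", "o3", "temp"),
    covariate_schema: Mapping[str, Sequence[str]] | None = None,
) -> Cohort:
    """Expand subject-level follow-up into per-calendar-year (start, stop] rows.

    Parameters
    ----------
    subjects : DataFrame
        ``subject_id`` plus one column per covariate.
    annual_exposures : DataFrame
        ``subject_id, year`` plus one column per exposure; one row per
        subject-calendar-year covering the whole follow-up window.
    followup : DataFrame
        ``subject_id, entry, exit, event`` with entry/exit as decimal calendar
        years; when ``event == 1`` the event time is ``exit``.

    Returns
    -------
    Cohort
        One record per subject-year slice on the time-on-study scale
        (``start = calendar_time - entry``).  Zero-length slices at exact year
        boundaries are not emitted; the event attaches to the final record.
        Person-time and event counts are conserved exactly.
    """
    if covariate_schema is None:
        covariate_schema = {
            c: sorted(subjects[c].astype(str).unique())
            for c in subjects.columns
            if c != "subject_id"
        }
    exp_cols = list(exposure_names)

    sid = followup["subject_id"].astype(str).to_numpy()
    entry = followup["entry"].to_numpy(dtype=float)
    exit_ = followup["exit"].to_numpy(dtype=float)
    ev = followup["event"].to_numpy(dtype=int)
    if np.any(exit_ <= entry):
        who = sid[np.flatnonzero(exit_ <= entry)[0]]
        raise ValidationError(f"subject {who!r}: exit <= entry")

    # one slice per calendar year overlapped; a subject censored exactly at a
    # year boundary contributes no zero-length slice
    y0 = np.floor(entry).astype(int)
    counts = np.ceil(exit_).astype(int) - y0
    counts = np.maximum(counts, 1)
    rep = np.repeat(np.arange(len(sid)), counts)
    offs = np.concatenate([np.arange(c) for c in counts])
    year = y0[rep] + offs
    a = np.maximum(entry[rep], year.astype(float))
    b = np.minimum(exit_[rep], year.astype(float) + 1.0)
    keep = b > a
    rep, year, a, b = rep[keep], year[keep], a[keep], b[keep]

    df = pd.DataFrame(
        {
            "subject_id": sid[rep],
            "start": a - entry[rep],
            "stop": b - entry[rep],
            "event": np.where(b == exit_[rep], ev[rep], 0),
            "year": year,
        }
    )
    exp_keyed = annual_exposures.copy()
    exp_keyed["subject_id"] = exp_keyed["subject_id"].astype(str)
    merged = df.merge(
        exp_keyed[["subject_id", "year", *exp_cols]],
        on=["subject_id", "year"],
        how="left",
        validate="many_to_one",
    )
    missing = merged[exp_cols[0]].isna() if exp_cols else pd.Series(False, index=merged.index)
    if missing.any():
        i = int(np.flatnonzero(missing.to_numpy())[0])
        raise ValidationError(
            f"missing exposure for subject {merged['subject_id'].iat[i]!r} "
            f"year {int(merged['year'].iat[i])}"
        )
    cov_cols = [c for c in subjects.columns if c != "subject_id"]
    subj_cov = subjects.copy()
    subj_cov["subject_id"] = subj_cov["subject_id"].astype(str)
    merged = merged.merge(subj_cov[["subject_id", *cov_cols]], on="subject_id",
                          how="left", validate="many_to_one")
    merged = merged.drop(columns=["year"])
    return Cohort(merged, exp_cols, {k: list(v) for k, v in covariate_schema.items()})


# ---------------------------------------------------------------------------
# quantization


def empirical_cuts(values: np.ndarray | pd.Series, exposure: str = "exposure") -> QuantileSpec:
    """Quartile cut points (type-7 percentiles) over person-period records."""
    x = np.asarray(values, dtype=float)
    q25, q50, q75 = np.percentile(x, [25.0, 50.0, 75.0])
    if not (q25 < q50 < q75):
        raise DegenerateQuantileError(
            f"{exposure}: degenerate quartiles ({q25}, {q50}, {q75})"
        )
    return QuantileSpec(exposure, (float(q25), float(q50), float(q75)), source="empirical")


def quantize(
    cohort: Cohort,
    exposure: str,
    spec: QuantileSpec | str = "empirical",
    column: str | None = None,
) -> tuple[Cohort, QuantileSpec]:
    """Add an integer quartile-score column (0-3) for one exposure.

    With ``spec="empirical"`` the cut points are the record-level 25/50/75th
    percentiles of the exposure across the whole cohort.  Returns a new Cohort
    (input is not mutated) and the spec used.
    """
    if exposure not in cohort.data.columns:
        raise SchemaError(f"exposure {exposure!r} not in cohort")
    if spec == "empirical":
        spec = empirical_cuts(cohort.data[exposure], exposure)
    assert isinstance(spec, QuantileSpec)
    df = cohort.data.copy()
    df[column or f"{exposure}_q"] = spec.apply(df[exposure])
    return Cohort(df, list(cohort.exposure_names), dict(cohort.covariate_schema)), spec


# ---------------------------------------------------------------------------
# design matrices


def design_matrix(
    cohort: Cohort,
    terms: Sequence[str],
) -> pd.DataFrame:
    """Build a float design matrix (no intercept; Cox needs none).

    Each term is either a numeric column (passed through, e.g. an exposure, a
    quartile score, or temperature) or a schema covariate, expanded to
    reference-coded dummies named ``cov[level]`` with the schema's first level
    as reference.
    """
    cols: dict[str, np.ndarray] = {}
    df = cohort.data
    for term in terms:
        if term in cohort.covariate_schema:
            levels = cohort.covariate_schema[term]
            vals = df[term].astype(str)
            for lev in levels[1:]:
                cols[f"{term}[{lev}]"] = (vals == lev).to_numpy(dtype=float)
        elif term in df.columns:
            cols[term] = df[term].to_numpy(dtype=float)
        else:
            raise SchemaError(f"unknown model term {term!r}")
    return pd.DataFrame(cols, index=df.index)
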