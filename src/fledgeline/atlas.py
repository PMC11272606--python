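"""Reading, filtering and encoding citizen-science breeding-bird observations.

Swiss breeding-bird monitoring records carry an integer "Atlas code"
describing the observed breeding behaviour (e.g. 13 = recently fledged
young, 16 = adult with food for nestlings).  For the fledging-phenology
analysis each record is encoded into a binary response: 1 if the brood is
certainly fledged, 0 if it is certainly or likely not fledged, and every
other code is excluded from the analysis (with a logged count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Atlas code -> binary fledging response.  Codes describing incubation,
#: nestlings or food-carrying adults count as "certainly or likely not
#: fledged" (0); recently fledged birds count as "certainly fledged" (1).
ATLAS_RESPONSE: dict[int, int] = {
    9: 0,   # female adult with breeding spot
    15: 0,  # adult carrying faecal sac from the nest
    16: 0,  # adult with food for nestlings
    18: 0,  # nest with breeding adult
    19: 0,  # nest with eggs or nestlings
    13: 1,  # recently fledged birds
}

#: Columns required of an observation table.
REQUIRED_COLUMNS = ("species", "date", "elevation_m", "year", "atlas_code")

#: Default elevational belts used for raw-proportion diagnostics (m a.s.l.);
#: three belts partitioning the 1500-2200 m study gradient.
DEFAULT_BELTS: tuple[tuple[float, float], ...] = (
    (1500, 1733),
    (1734, 1967),
    (1968, 2200),
)


def encode_response(atlas_code: int) -> int | None:
    """Map one Atlas code to the binary fledging response.

    Returns 1 (certainly fledged), 0 (certainly or likely not fledged) or
    ``None`` when the code is outside the analysis mapping and the record
    must be excluded.

    Raises
    ------
    TypeError
        If ``atlas_code`` is not an integer (booleans are rejected too).
    """
    if isinstance(atlas_code, bool) or not isinstance(
        atlas_code, (int, np.integer)
    ):
        raise TypeError(
            f"atlas_code must be an integer, got {type(atlas_code).__name__}"
        )
    return ATLAS_RESPONSE.get(int(atlas_code))


def encode_responses(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[int, int]]:
    """Encode the ``atlas_code`` column of an observation table.

    Returns the table with ``response`` (float, NaN when excluded) and
    ``excluded_reason`` columns added, plus a per-code count of excluded
    records.  Retained + excluded always equals the input row count.
    """
    out = records.copy()
    codes = out["atlas_code"].astype(int)
    out["response"] = codes.map(ATLAS_RESPONSE).astype(float)
    excluded = out["response"].isna()
    out["excluded_reason"] = np.where(excluded, "atlas_code_unmapped", "")
    excl_counts = (
        codes[excluded].value_counts().sort_index().to_dict() if excluded.any() else {}
    )
    if excl_counts:
        logger.info(
            "excluded %d records with unmapped Atlas codes: %s",
            int(excluded.sum()),
            excl_counts,
        )
    return out, excl_counts


@dataclass
class ReadReport:
    """Row-level issues found while reading an observation file."""

    n_rows: int = 0
    n_valid: int = 0
    row_errors: list[tuple[int, str]] = field(default_factory=list)


def read_observations(
    path,
    schema: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read an observation CSV into a validated table.

    Parameters
    ----------
    path : str or path-like
        CSV with header row and columns ``species, date, elevation_m,
        year, atlas_code`` (ISO-8601 dates).  Extra columns (e.g. x/y
        coordinates) are passed through untouched.
    schema : dict, optional
        Mapping from the file's column names to the canonical names, for
        extracts using different headers.

    Returns
    -------
    (DataFrame, ReadReport)
        Table with a ``doy`` column computed from ``date`` under the
        proleptic Gregorian calendar (leap years give DOY up to 366).
        Malformed rows are reported with their (0-based) row numbers in
        the report and dropped from the table, never silently.

    Raises
    ------
    ValueError
        If a required column is missing after renaming.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation table missing required columns: {missing}")

    report = ReadReport(n_rows=len(df))
    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    bad_dates = dates.isna()
    for idx in df.index[bad_dates]:
        report.row_errors.append((int(idx), f"unparseable date {df.at[idx, 'date']!r}"))

    elev = pd.to_numeric(df["elevation_m"], errors="coerce")
    bad_elev = elev.isna()
    for idx in df.index[bad_elev & ~bad_dates]:
        report.row_errors.append(
            (int(idx), f"non-numeric elevation {df.at[idx, 'elevation_m']!r}")
        )

    ok = ~(bad_dates | bad_elev)
    out = df.loc[ok].copy()
    out["date"] = dates[ok]
    out["elevation_m"] = elev[ok]
    out["doy"] = out["date"].dt.dayofyear.astype(int)
    out["year"] = out["year"].astype(int)
    out["atlas_code"] = out["atlas_code"].astype(int)
    report.n_valid = len(out)
    if report.row_errors:
        logger.warning("dropped %d malformed rows", len(report.row_errors))
    return out.reset_index(drop=True), report


def filter_observations(
    records: pd.DataFrame,
    species: str | None = None,
    elev_range: tuple[float, float] = (1500.0, 2200.0),
    year_range: tuple[int, int] = (2013, 2022),
) -> pd.DataFrame:
    """Restrict an observation table to one species, elevation and year window.

    Both ranges are closed intervals: a record at exactly 1500 m or 2200 m
    is retained.  An empty result triggers a warning, not an error.
    """
    n0 = len(records)
    mask = (
        records["elevation_m"].between(*elev_range)
        & records["year"].between(*year_range)
    )
    if species is not None:
        mask &= records["species"] == species
    out = records.loc[mask].reset_index(drop=True)
    logger.info(
        "filter species=%s elev=%s years=%s: %d -> %d records",
        species, elev_range, year_range, n0, len(out),
    )
    if len(out) == 0:
        logger.warning("filter produced an empty observation table")
    return out


def binomial_interval(
    k: np.ndarray | int,
    n: np.ndarray | int,
    level: float = 0.95,
    prior: str = "uniform",
) -> tuple[np.ndarray, np.ndarray]:
    """Bayesian binomial compatibility interval for k successes out of n.

    Posterior is Beta(k + a, n - k + a) with a = 1 (uniform prior, the
    default) or a = 1/2 (Jeffreys).  Returns the (lower, upper) central
    quantiles at the requested level.
    """
    a = {"uniform": 1.0, "jeffreys": 0.5}[prior]
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    tail = (1.0 - level) / 2.0
    lo = stats.beta.ppf(tail, k + a, n - k + a)
    hi = stats.beta.ppf(1.0 - tail, k + a, n - k + a)
    return lo, hi


def binned_raw_proportions(
    records: pd.DataFrame,
    bin_width: int = 20,
    belts: tuple[tuple[float, float], ...] = DEFAULT_BELTS,
    prior: str = "uniform",
) -> pd.DataFrame:
    """Raw fledged proportions over day-of-year bins per elevational belt.

    A model-free diagnostic: per (belt, 20-day bin) the proportion
    ``p_hat = k/n`` of certainly-fledged records, with Bayesian binomial
    compatibility intervals.  Empty bins are emitted with ``n = 0`` and
    undefined ``p_hat`` so the season stays contiguous.
    """
    df = records.dropna(subset=["response"])
    lo_doy = int(df["doy"].min()) if len(df) else 1
    hi_doy = int(df["doy"].max()) if len(df) else bin_width
    edges = np.arange(lo_doy, hi_doy + bin_width, bin_width)
    if edges[-1] <= hi_doy:
        edges = np.append(edges, edges[-1] + bin_width)

    rows = []
    for belt_lo, belt_hi in belts:
        belt_df = df[df["elevation_m"].between(belt_lo, belt_hi)]
        for left, right in zip(edges[:-1], edges[1:]):
            # right-open bins so consecutive bins never overlap
            sel = belt_df[(belt_df["doy"] >= left) & (belt_df["doy"] < right)]
            n = len(sel)
            k = int(sel["response"].sum())
            if n > 0:
                ci_lo, ci_hi = binomial_interval(k, n, prior=prior)
                p_hat = k / n
            else:
                p_hat, ci_lo, ci_hi = np.nan, np.nan, np.nan
            rows.append(
                {
                    "belt_low_m": belt_lo,
                    "belt_high_m": belt_hi,
                    "bin_start_doy": int(left),
                    "bin_end_doy": int(right),
                    "n": n,
                    "k": k,
                    "p_hat": p_hat,
                    "ci_low": float(ci_lo),
                    "ci_high": float(ci_hi),
                }
            )
    return pd.DataFrame(rows)


def write_observations(records: pd.DataFrame, path) -> None:
    """Write an observation table (with response/excluded_reason) to CSV."""
    out = records.copy()
    if "date" in out.columns:
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
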