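"""Phenotype file reading/writing, validation and trait summaries.

The phenotype table is delimited text (comma default, tab accepted) with one
row per animal: ``id``, ``year``, ``environment``, repeated body-weight (g)
and total-length (cm) columns named W1..W6 / L1..L6 (ages 105-570 days
post-hatch), and a 0/1 ``survival`` flag.  Missing cells are allowed
anywhere ("NA" or empty).  Machine-clean numbers only: thousands separators
are rejected.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeError",
    "read_phenotypes",
    "write_phenotypes",
    "attach_parents",
    "summarize",
    "format_summary",
]

_TRAIT_RE = re.compile(r"^[WL]\d+$", re.IGNORECASE)


class PhenotypeError(ValueError):
    pass


def _trait_columns(columns) -> list:
    return [c for c in columns if _TRAIT_RE.match(str(c))]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read and validate a phenotype table.

    Trait cells must be numeric (or missing); weights and lengths must be
    strictly positive; survival must be 0/1.  Violations are reported with
    the offending row (1-based, excluding the header) and column.
    """
    raw = pd.read_csv(path, sep=None, engine="python", dtype=object,
                      skip_blank_lines=True)
    raw.columns = [str(c).strip() for c in raw.columns]
    if "id" not in [c.lower() for c in raw.columns]:
        raise PhenotypeError("phenotype file has no 'id' column")
    raw = raw.rename(columns={c: c.lower() if c.lower() in
                              ("id", "year", "environment", "survival", "sire",
                               "dam", "family") else c
                              for c in raw.columns})
    if len(raw) == 0:
        warnings.warn("phenotype file has an empty data section", stacklevel=2)

    traits = _trait_columns(raw.columns)
    for col in traits + (["survival"] if "survival" in raw.columns else []):
        parsed = []
        for i, v in enumerate(raw[col]):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                parsed.append(np.nan)
                continue
            s = str(v).strip()
            if s in ("", "NA", "NaN", "na", "nan", "."):
                parsed.append(np.nan)
                continue
            if "," in s:
                raise PhenotypeError(
                    f"row {i + 1}, column {col!r}: thousands separators are "
                    f"not accepted ({s!r})"
                )
            try:
                x = float(s)
            except ValueError:
                raise PhenotypeError(
                    f"row {i + 1}, column {col!r}: non-numeric value {s!r}"
                ) from None
            parsed.append(x)
        vals = np.array(parsed, dtype=float)
        if col == "survival":
            bad = ~np.isnan(vals) & ~np.isin(vals, (0.0, 1.0))
            if bad.any():
                i = int(np.where(bad)[0][0])
                raise PhenotypeError(
                    f"row {i + 1}, column 'survival': value {vals[i]} outside {{0,1}}"
                )
        else:
            bad = ~np.isnan(vals) & (vals <= 0)
            if bad.any():
                i = int(np.where(bad)[0][0])
                raise PhenotypeError(
                    f"row {i + 1}, column {col!r}: non-positive measurement "
                    f"{vals[i]}"
                )
        raw[col] = vals

    # other columns: adopt a numeric parse when it is lossless, so ad-hoc
    # trait names (e.g. "weight") behave like the standard W#/L# columns
    reserved = {"id", "environment", "family"}
    for col in raw.columns:
        if col in reserved or col in traits or col == "survival":
            continue
        as_str = raw[col].astype(str).str.strip()
        missing = raw[col].isna() | as_str.isin(["", "NA", "NaN", "na", "nan", "."])
        num = pd.to_numeric(as_str.where(~missing), errors="coerce")
        if not (num.isna() & ~missing).any():
            raw[col] = num
    return raw


def write_phenotypes(table: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    table.to_csv(path, sep=sep, index=False, na_rep="NA")


def attach_parents(data: pd.DataFrame, ped) -> pd.DataFrame:
    """Merge sire/dam codes and a full-sib family label from a pedigree into
    a phenotype table (needed by the sire-dam models when the file carries
    only animal ids)."""
    lookup = {o: (s, d) for o, s, d in zip(ped.original_id, ped.sire, ped.dam)}
    out = data.copy()
    sires, dams, fams = [], [], []
    for i in out["id"]:
        key = i
        if key not in lookup:
            key = str(i)
            if key not in lookup:
                raise PhenotypeError(f"animal {i!r} not in pedigree")
        s, d = lookup[key]
        sires.append(s)
        dams.append(d)
        fams.append(f"{s}x{d}")
    out["sire"], out["dam"], out["family"] = sires, dams, fams
    return out


def summarize(table: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Per-trait n, mean, SD, CV (%), min, max.

    SD is the sample (n-1) standard deviation and CV = 100*SD/mean; a zero
    mean leaves CV undefined (NaN).  Binary survival is summarized on the
    0/1 scale (its mean is the alive fraction).
    """
    if len(table) == 0:
        raise PhenotypeError("cannot summarize an empty table")
    if traits is None:
        reserved = {"id", "year", "environment", "sire", "dam", "family",
                    "survival"}
        traits = [
            c for c in table.columns
            if c not in reserved
            and (_TRAIT_RE.match(str(c)) or pd.api.types.is_numeric_dtype(table[c]))
        ]
        if "survival" in table.columns:
            traits = traits + ["survival"]
    rows = []
    for t in traits:
        x = pd.to_numeric(table[t], errors="coerce").dropna().to_numpy()
        n = len(x)
        if n == 0:
            rows.append({"trait": t, "n": 0, "mean": np.nan, "sd": np.nan,
                         "cv": np.nan, "min": np.nan, "max": np.nan})
            continue
        mean = x.mean()
        sd = x.std(ddof=1) if n > 1 else 0.0
        cv = 100.0 * sd / mean if mean != 0 else np.nan
        rows.append({"trait": t, "n": n, "mean": mean, "sd": sd, "cv": cv,
                     "min": x.min(), "max": x.max()})
    return pd.DataFrame(rows)


def survival_percent(table: pd.DataFrame, n_stocked: int | None = None) -> dict:
    """Survival summarized two ways: the mean of the 0/1 flag, and — when a
    stocking count is supplied — the percent difference between the number
    stocked and the number alive at final harvest."""
    alive = pd.to_numeric(table["survival"], errors="coerce")
    out = {"mean_pct": float(100.0 * alive.mean())}
    if n_stocked is not None:
        n_alive = int(alive.fillna(0).sum())
        out["stocking_loss_pct"] = float(100.0 * (n_stocked - n_alive) / n_stocked)
    return out


def format_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Display copy rounded to one decimal (report precision); the full
    precision table is what computations should use."""
    out = summary.copy()
    for c in ("mean", "sd", "cv", "min", "max"):
        out[c] = out[c].round(1)
    return out
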