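"""Twin-pair datasets: container, CSV I/O, covariate residualization, descriptives.

The canonical layout is *wide*, one row per twin pair: a zygosity column
(``MZ``/``DZ``), per-twin item columns named ``<item>_t1`` / ``<item>_t2``,
optional per-twin covariates (``age_t1``, ``age_t2``, ``sex_t1``, ``sex_t2``)
and an optional pair-level ``moderator`` column (e.g. childhood SES).
The twin literature's double-entry format is available as an export only.

Missing cells stay missing throughout; no imputation happens anywhere in this
package — downstream model fitting is full-information maximum likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MZ = "MZ"
DZ = "DZ"
GROUPS = (MZ, DZ)

_RESERVED_BASES = {"age", "sex"}


class SchemaError(ValueError):
    """A mandatory column is absent or the schema is malformed."""


class PhenotypeParseError(ValueError):
    """A phenotype cell could not be parsed as a number."""


class SingularDesignError(ValueError):
    """The residualization design matrix is rank deficient."""


@dataclass
class TwinDataset:
    """Wide, one-row-per-pair twin dataset.

    Parameters
    ----------
    frame : pandas.DataFrame
        Canonical wide table. Must contain ``zygosity`` plus
        ``<item>_t1``/``<item>_t2`` for every item in `items`.
    items : list of str
        Base names of the phenotype items (p of them).
    """

    frame: pd.DataFrame
    items: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "zygosity" not in self.frame.columns:
            raise SchemaError("frame lacks a 'zygosity' column")
        for it in self.items:
            for suf in ("_t1", "_t2"):
                if it + suf not in self.frame.columns:
                    raise SchemaError(f"frame lacks phenotype column {it + suf!r}")
        bad = set(self.frame["zygosity"]) - set(GROUPS)
        if bad:
            raise SchemaError(f"unknown zygosity codes {sorted(bad)}")
        if {"sex_t1", "sex_t2"}.issubset(self.frame.columns):
            mz = self.frame["zygosity"] == MZ
            opp = mz & self.frame["sex_t1"].notna() & self.frame["sex_t2"].notna() \
                & (self.frame["sex_t1"] != self.frame["sex_t2"])
            if opp.any():
                logger.warning("dropping %d opposite-sex MZ pair(s)", int(opp.sum()))
                self.frame = self.frame.loc[~opp].reset_index(drop=True)

    # -- basic accessors ----------------------------------------------------

    @property
    def p(self) -> int:
        return len(self.items)

    @property
    def n_pairs(self) -> int:
        return len(self.frame)

    @property
    def n_mz(self) -> int:
        return int((self.frame["zygosity"] == MZ).sum())

    @property
    def n_dz(self) -> int:
        return int((self.frame["zygosity"] == DZ).sum())

    @property
    def has_moderator(self) -> bool:
        return "moderator" in self.frame.columns

    def group_frame(self, group: str) -> pd.DataFrame:
        if group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        return self.frame.loc[self.frame["zygosity"] == group]

    def phenotypes(self, group: str | None = None) -> np.ndarray:
        """(n, 2p) float array ordered [twin-1 items, twin-2 items]; NaN = missing."""
        fr = self.frame if group is None else self.group_frame(group)
        cols = [it + "_t1" for it in self.items] + [it + "_t2" for it in self.items]
        return fr[cols].to_numpy(dtype=float)

    def moderator_values(self, group: str | None = None) -> np.ndarray:
        if not self.has_moderator:
            raise ValueError("dataset has no moderator column")
        fr = self.frame if group is None else self.group_frame(group)
        return fr["moderator"].to_numpy(dtype=float)

    def copy(self) -> "TwinDataset":
        return TwinDataset(self.frame.copy(), list(self.items))

    # -- I/O ----------------------------------------------------------------

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_double_entry(self) -> pd.DataFrame:
        """Export in double-entry (each pair twice, twin order swapped)."""
        a = self.frame.copy()
        b = self.frame.copy()
        for it in self.items + sorted(_RESERVED_BASES & _covariate_bases(self.frame)):
            b[it + "_t1"], b[it + "_t2"] = a[it + "_t2"], a[it + "_t1"]
        out = pd.concat([a, b], ignore_index=True)
        out["entry"] = np.r_[np.ones(len(a), int), 2 * np.ones(len(b), int)]
        return out


def _covariate_bases(frame: pd.DataFrame) -> set[str]:
    return {b for b in _RESERVED_BASES
            if b + "_t1" in frame.columns and b + "_t2" in frame.columns}


# ---------------------------------------------------------------------------
# loading


def _load_schema(schema) -> dict:
    if schema is None:
        return {}
    if isinstance(schema, Mapping):
        return dict(schema)
    with open(schema) as fh:
        return yaml.safe_load(fh) or {}


def load_twin_table(path, schema=None) -> TwinDataset:
    """Read a wide twin-pair CSV into a :class:`TwinDataset`.

    `schema` (dict, or path to a YAML file) maps file columns onto the
    canonical layout::

        zygosity: zyg                 # mandatory
        zygosity_map: {"1": MZ, "2": DZ}   # optional recoding
        items:                        # mandatory: base -> [twin1 col, twin2 col]
          item1: [g1_a, g1_b]
        age: [age_a, age_b]           # optional covariates
        sex: [sex_a, sex_b]
        moderator: ses
        pair_id: famid

    With ``schema=None`` the file is assumed to already use canonical column
    names, and items are inferred from matching ``*_t1``/``*_t2`` pairs.

    Rows whose zygosity is missing/unrecognized, and rows where neither twin
    has a single non-missing phenotype, are dropped with a logged count.
    """
    raw = pd.read_csv(path)
    cfg = _load_schema(schema)

    zcol = cfg.get("zygosity", "zygosity")
    if zcol not in raw.columns:
        raise SchemaError(f"zygosity column {zcol!r} not found in {path}")

    if "items" in cfg:
        item_map = {k: tuple(v) for k, v in cfg["items"].items()}
    else:
        bases = sorted(
            c[:-3] for c in raw.columns
            if c.endswith("_t1") and c[:-3] + "_t2" in raw.columns
            and c[:-3] not in _RESERVED_BASES
        )
        if not bases:
            raise SchemaError("no *_t1/*_t2 item column pairs found and no schema given")
        item_map = {b: (b + "_t1", b + "_t2") for b in bases}

    frame = pd.DataFrame()
    if cfg.get("pair_id", "pair_id" if "pair_id" in raw.columns else None):
        frame["pair_id"] = raw[cfg.get("pair_id", "pair_id")]

    zyg = raw[zcol].astype("string").str.strip()
    zmap = {str(k): v for k, v in cfg.get("zygosity_map", {}).items()}
    if zmap:
        zyg = zyg.map(lambda z: zmap.get(z, z))
    zyg = zyg.str.upper()
    ok = zyg.isin(GROUPS)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("dropped %d row(s) with unknown zygosity", n_bad)
    frame["zygosity"] = zyg

    items = list(item_map)
    for base, (c1, c2) in item_map.items():
        for col, suf in ((c1, "_t1"), (c2, "_t2")):
            if col not in raw.columns:
                raise SchemaError(f"item column {col!r} not found in {path}")
            try:
                frame[base + suf] = pd.to_numeric(raw[col], errors="raise")
            except (ValueError, TypeError):
                parsed = pd.to_numeric(raw[col], errors="coerce")
                bad_row = int((parsed.isna() & raw[col].notna()).idxmax())
                raise PhenotypeParseError(
                    f"non-numeric phenotype in column {col!r}, row {bad_row}: "
                    f"{raw[col].iloc[bad_row]!r}"
                ) from None

    for base in ("age", "sex"):
        if base in cfg:
            c1, c2 = cfg[base]
            frame[base + "_t1"], frame[base + "_t2"] = raw[c1], raw[c2]
        elif base + "_t1" in raw.columns and base + "_t2" in raw.columns:
            frame[base + "_t1"], frame[base + "_t2"] = raw[base + "_t1"], raw[base + "_t2"]
    mcol = cfg.get("moderator", "moderator" if "moderator" in raw.columns else None)
    if mcol:
        frame["moderator"] = pd.to_numeric(raw[mcol], errors="coerce")

    frame = frame.loc[ok].reset_index(drop=True)

    pheno_cols = [b + s for b in items for s in ("_t1", "_t2")]
    empty = frame[pheno_cols].isna().all(axis=1)
    if empty.any():
        logger.warning("dropped %d pair(s) with no phenotype data at all", int(empty.sum()))
        frame = frame.loc[~empty].reset_index(drop=True)

    ds = TwinDataset(frame, items)
    logger.info("loaded %d pairs (%d MZ, %d DZ), %d item(s)",
                ds.n_pairs, ds.n_mz, ds.n_dz, ds.p)
    return ds


# ---------------------------------------------------------------------------
# residualization


def _code_sex(values: pd.Series) -> pd.Series:
    if values.dtype.kind in "if":
        return values.astype(float)
    cats = sorted(values.dropna().astype(str).str.lower().unique())
    mapping = {c: float(i) for i, c in enumerate(cats)}
    return values.astype(str).str.lower().map(mapping).astype(float)


def residualize(data: TwinDataset, covariates: Sequence[str] = ("age", "sex")) -> TwinDataset:
    """Replace each phenotype by its OLS residual on the given covariates.

    Both twins enter as separate observations of a single pooled regression
    per item (intercept included), so residuals are exactly mean-centred and
    orthogonal to every covariate. Missing phenotype cells stay missing; the
    pair structure is untouched. Residualizing twice equals residualizing once.
    """
    covariates = list(covariates)
    if not set(covariates) <= _RESERVED_BASES:
        raise ValueError(f"covariates must be a subset of {sorted(_RESERVED_BASES)}")
    fr = data.frame.copy()

    # stacked individual-level design: row i of twin 1 block, then twin 2 block
    cols = []
    for base in covariates:
        c1, c2 = base + "_t1", base + "_t2"
        if c1 not in fr.columns or c2 not in fr.columns:
            raise SchemaError(f"covariate columns for {base!r} not present")
        v1 = _code_sex(fr[c1]) if base == "sex" else fr[c1].astype(float)
        v2 = _code_sex(fr[c2]) if base == "sex" else fr[c2].astype(float)
        cols.append(np.concatenate([v1.to_numpy(), v2.to_numpy()]))
    X = np.column_stack([np.ones(2 * len(fr))] + cols)

    for it in data.items:
        y = np.concatenate([fr[it + "_t1"].to_numpy(float), fr[it + "_t2"].to_numpy(float)])
        use = ~np.isnan(y)
        if np.isnan(X[use]).any():
            raise ValueError(
                f"missing covariate value for an individual with observed {it!r}"
            )
        Xu = X[use]
        if np.linalg.matrix_rank(Xu) < Xu.shape[1]:
            raise SingularDesignError("constant or collinear covariate in residualization")
        beta, *_ = np.linalg.lstsq(Xu, y[use], rcond=None)
        resid = np.full_like(y, np.nan)
        resid[use] = y[use] - Xu @ beta
        n = len(fr)
        fr[it + "_t1"], fr[it + "_t2"] = resid[:n], resid[n:]

    return TwinDataset(fr, list(data.items))


# ---------------------------------------------------------------------------
# descriptives


@dataclass
class DescriptiveTable:
    """Per-item, per-zygosity means/SDs and twin-1-twin-2 correlations.

    ``table`` has one row per item with columns
    ``{mz,dz}_{mean,sd}_{t1,t2}``, ``r_{mz,dz}``, ``se_{mz,dz}``, ``n_{mz,dz}``;
    ``avg_r`` holds the group-average item correlation.
    """

    table: pd.DataFrame
    avg_r: dict[str, float]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _pair_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    se = (1.0 - r * r) / np.sqrt(n - 2)  # documented convention; see module docs
    return r, se, n


def descriptives(data: TwinDataset) -> DescriptiveTable:
    """Table of per-item means, SDs and cross-twin Pearson correlations.

    Correlations use pairs complete on that item; fewer than 3 complete pairs
    yields an undefined (NaN) correlation rather than an error. The SE
    convention is (1 - r^2) / sqrt(n - 2).
    """
    rows = {}
    for it in data.items:
        row = {}
        for group in GROUPS:
            g = group.lower()
            fr = data.group_frame(group)
            x = fr[it + "_t1"].to_numpy(float)
            y = fr[it + "_t2"].to_numpy(float)
            row[f"{g}_mean_t1"] = np.nanmean(x) if np.isfinite(x).any() else np.nan
            row[f"{g}_sd_t1"] = np.nanstd(x, ddof=1) if np.isfinite(x).sum() > 1 else np.nan
            row[f"{g}_mean_t2"] = np.nanmean(y) if np.isfinite(y).any() else np.nan
            row[f"{g}_sd_t2"] = np.nanstd(y, ddof=1) if np.isfinite(y).sum() > 1 else np.nan
            r, se, n = _pair_corr(x, y)
            row[f"r_{g}"], row[f"se_{g}"], row[f"n_{g}"] = r, se, n
        rows[it] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    avg = {}
    for group in GROUPS:
        rs = table[f"r_{group.lower()}"].to_numpy()
        avg[group] = float(np.nanmean(rs)) if np.isfinite(rs).any() else np.nan
    return DescriptiveTable(table=table, avg_r=avg)
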