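"""Data containers, CSV I/O, functional-group aggregation and unit conversions.

The analytical unit is a site-by-taxon (or site-by-functional-group) table of
count densities in individuals per litre, carrying reservoir and season
metadata per site.  Functional groups follow the Reynolds/Padisák coda
(A, D, H1, L0, M, MP, P, S1, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default set of recognised functional-group coda.  Extensible via the
#: ``extra_codes`` argument of :class:`FunctionalGroupMap`.
CODA = frozenset(
    {"A", "D", "E", "F", "H1", "J", "K", "L0", "M", "MP", "N", "P", "S1", "SN", "X1", "X2", "Y"}
)

#: Metadata columns expected immediately after ``site_id`` in CSV files.
META_COLUMNS = ("reservoir", "season")

#: Canonical hydrological seasons; spring/summer map to wet, autumn/winter to dry.
SEASON_TO_WETDRY = {
    "spring": "wet",
    "summer": "wet",
    "autumn": "dry",
    "winter": "dry",
    "wet": "wet",
    "dry": "dry",
}


class ValidationError(ValueError):
    """Raised when a table violates its structural invariants."""


def _check_counts(values: pd.DataFrame, what: str) -> None:
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~np.isfinite(numeric)
    if bad.to_numpy().any():
        row, col = next(zip(*np.nonzero(bad.to_numpy())))
        raise ValidationError(
            f"{what}: non-numeric or non-finite value at "
            f"(site {values.index[row]!r}, column {values.columns[col]!r})"
        )
    if (numeric.to_numpy() < 0).any():
        row, col = next(zip(*np.nonzero((numeric < 0).to_numpy())))
        raise ValidationError(
            f"{what}: negative density at (site {values.index[row]!r}, "
            f"column {values.columns[col]!r})"
        )


def _check_index(values: pd.DataFrame, what: str) -> None:
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise ValidationError(f"{what}: duplicate site ids {dups}")
    if values.columns.has_duplicates:
        dups = values.columns[values.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{what}: duplicate column ids {dups}")


@dataclass
class AbundanceTable:
    """Site × taxon count densities (ind./L) with per-site metadata.

    ``values`` is indexed by site_id with one column per taxon; ``meta`` is
    indexed identically with ``reservoir`` and ``season`` columns.  Absence is
    an explicit zero — missing values are not permitted.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_index(self.values, type(self).__name__)
        _check_counts(self.values, type(self).__name__)
        self.values = self.values.astype(float)
        if not self.meta.index.equals(self.values.index):
            raise ValidationError("meta site_ids do not match value site_ids")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise ValidationError(f"meta is missing required column {col!r}")

    @property
    def sites(self) -> pd.Index:
        return self.values.index

    @property
    def units(self) -> pd.Index:
        """Taxon (or functional-group) column labels."""
        return self.values.columns

    def subset(self, site_ids) -> "AbundanceTable":
        return type(self)(self.values.loc[site_ids], self.meta.loc[site_ids])

    def strata(self):
        """Iterate over (reservoir, season) → sub-table."""
        for key, grp in self.meta.groupby(["reservoir", "season"], sort=True, observed=True):
            yield key, self.subset(grp.index)


@dataclass
class FGTable(AbundanceTable):
    """Site × functional-group table; optional biomass layer (mg/L)."""

    biomass: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.biomass is not None:
            _check_index(self.biomass, "FGTable biomass")
            _check_counts(self.biomass, "FGTable biomass")
            self.biomass = self.biomass.astype(float)
            if not self.biomass.index.equals(self.values.index):
                raise ValidationError("biomass site_ids do not match abundance site_ids")

    def layer(self, metric: str) -> pd.DataFrame:
        if metric == "abundance":
            return self.values
        if metric == "biomass":
            if self.biomass is None:
                raise ValidationError("FGTable has no biomass layer")
            return self.biomass
        raise ValueError(f"unknown metric {metric!r} (expected 'abundance' or 'biomass')")

    def subset(self, site_ids) -> "FGTable":
        bio = None if self.biomass is None else self.biomass.loc[site_ids]
        return FGTable(self.values.loc[site_ids], self.meta.loc[site_ids], bio)


@dataclass
class FunctionalGroupMap:
    """taxon id → functional-group code, restricted to the declared coda."""

    mapping: dict[str, str]
    extra_codes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        allowed = CODA | set(self.extra_codes)
        bad = {t: c for t, c in self.mapping.items() if c not in allowed}
        if bad:
            raise ValidationError(f"functional-group codes outside coda set: {bad}")

    @classmethod
    def from_csv(cls, path, extra_codes=()) -> "FunctionalGroupMap":
        df = pd.read_csv(path, dtype=str)
        if df.shape[1] < 2:
            raise ValidationError(f"{path}: FG map needs two columns (taxon, fg)")
        taxa, fgs = df.iloc[:, 0], df.iloc[:, 1]
        if taxa.duplicated().any():
            raise ValidationError(f"{path}: duplicate taxa {taxa[taxa.duplicated()].tolist()}")
        return cls(dict(zip(taxa, fgs)), frozenset(extra_codes))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"taxon": list(self.mapping), "fg": list(self.mapping.values())}
        ).to_csv(path, index=False)


@dataclass
class EnvTable:
    """Site × environmental-variable table (WT, DO, pH, SAL, COND, TDS, ...).

    Missing sensor values are permitted (NaN) and excluded pairwise downstream.
    """

    values: pd.DataFrame

    BOUNDED = {"pH": (0.0, 14.0)}
    NON_NEGATIVE = ("DO", "COND", "TDS", "SAL", "transparency")

    def __post_init__(self) -> None:
        _check_index(self.values, "EnvTable")
        self.values = self.values.apply(pd.to_numeric, errors="coerce").astype(float)
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            raise ValidationError("EnvTable: infinite value present")
        for col, (lo, hi) in self.BOUNDED.items():
            if col in self.values.columns:
                v = self.values[col].dropna()
                if ((v <= lo) | (v >= hi)).any():
                    raise ValidationError(f"EnvTable: {col} outside ({lo}, {hi})")
        for col in self.NON_NEGATIVE:
            if col in self.values.columns and (self.values[col].dropna() < 0).any():
                raise ValidationError(f"EnvTable: negative {col}")

    @property
    def sites(self) -> pd.Index:
        return self.values.index


# ---------------------------------------------------------------------------
# CSV I/O


def read_abundance(path, cls=AbundanceTable):
    """Read a site × taxon CSV (site_id, reservoir, season, taxa...).

    Row and column order are preserved as read.
    """
    df = pd.read_csv(path)
    if df.shape[1] < len(META_COLUMNS) + 1:
        raise ValidationError(f"{path}: expected site_id, {', '.join(META_COLUMNS)}, taxa columns")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "site_id"
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {missing}")
    meta = df[list(META_COLUMNS)].astype(str)
    values = df.drop(columns=list(META_COLUMNS))
    return cls(values, meta)


def write_abundance(tab: AbundanceTable, path) -> None:
    """Write a table in the same CSV layout ``read_abundance`` accepts."""
    out = pd.concat([tab.meta[list(META_COLUMNS)], tab.values], axis=1)
    out.index.name = "site_id"
    out.to_csv(path)


def read_fg_table(path, biomass_path=None) -> FGTable:
    tab = read_abundance(path, cls=AbundanceTable)
    biomass = None
    if biomass_path is not None:
        biomass = read_abundance(biomass_path).values
    return FGTable(tab.values, tab.meta, biomass)


def read_env(path) -> EnvTable:
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "site_id"
    df = df.drop(columns=[c for c in META_COLUMNS if c in df.columns])
    return EnvTable(df)


def write_env(env: EnvTable, path) -> None:
    env.values.to_csv(path)


# ---------------------------------------------------------------------------
# Aggregation and unit conversions


def aggregate_to_fg(tab: AbundanceTable, fg_map: FunctionalGroupMap, strict: bool = True) -> FGTable:
    """Sum taxon columns into functional-group columns per site.

    In strict mode every taxon must be mapped and per-site totals are
    conserved; with ``strict=False`` unmapped taxa are dropped with a warning.
    """
    unmapped = [t for t in tab.units if t not in fg_map.mapping]
    if unmapped:
        if strict:
            raise ValidationError(f"unmapped taxa: {unmapped}")
        logger.warning("dropping %d unmapped taxa: %s", len(unmapped), unmapped)
    mapped = [t for t in tab.units if t in fg_map.mapping]
    # groupby on the column axis preserves first-appearance FG order
    codes = [fg_map.mapping[t] for t in mapped]
    fg_order = list(dict.fromkeys(codes))
    values = tab.values[mapped].T.groupby(np.array(codes)).sum().T[fg_order]
    return FGTable(values, tab.meta.copy())


def cells_per_litre(n1: float, v0: float, v1: float) -> float:
    """Density in ind./L from a chamber count: N = 10·V0/(3·V1) × N1.

    ``n1`` cells counted over the 30 grid rows of a 0.1 mL chamber, from a
    sample concentrated to ``v0`` mL, of which ``v1`` mL was loaded.
    """
    if v0 <= 0 or v1 <= 0:
        raise ValueError(f"volumes must be positive (V0={v0}, V1={v1})")
    if n1 < 0:
        raise ValueError(f"counted cells must be non-negative (N1={n1})")
    return 10.0 * v0 / (3.0 * v1) * n1


def biovolume_to_biomass(v: float, factor: float = 1.0) -> float:
    """Convert total biovolume (mm³/L) to wet-weight biomass (mg/L).

    The default factor 1.0 encodes the convention that 1 mm³ of algal cell
    volume weighs approximately 1 mg.
    """
    if v < 0:
        raise ValueError(f"biovolume must be non-negative (got {v})")
    return v * factor


def canonical_season(label: str) -> str:
    """Map a four-season label to the wet/dry dichotomy."""
    key = str(label).strip().lower()
    if key not in SEASON_TO_WETDRY:
        raise ValidationError(f"unknown season label {label!r}")
    return SEASON_TO_WETDRY[key]
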