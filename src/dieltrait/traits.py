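"""Species trait table: schema, I/O, transforms and collinearity diagnostics.

The trait set follows the comparative mammal analyses this package supports:
a dominant diel niche (nocturnal / crepuscular / cathemeral / diurnal), a
diel-flexibility flag, and five functional traits — body mass (g), litter
size, a continuous diet trait derived from ten semi-quantitative diet
categories, foraging stratum (ordinal 1..4: ground, scansorial, arboreal,
aerial) and habitat breadth (count of suitable habitats).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIEL_NICHES = ("nocturnal", "crepuscular", "cathemeral", "diurnal")
FORAGING_STRATA = {1: "ground", 2: "scansorial", 3: "arboreal", 4: "aerial"}

#: the five analysis traits, on their raw scales
TRAIT_COLUMNS = (
    "body_mass_g",
    "litter_size",
    "diet",
    "foraging_stratum",
    "habitat_breadth",
)

#: names of the transformed/standardised trait columns
TRANSFORMED_COLUMNS = (
    "body_mass",
    "litter_size",
    "diet",
    "foraging_stratum",
    "habitat_breadth",
)

_META_COLUMNS = ("species_id", "order", "family", "diel_niche", "diel_flexible")
_NA_TOKENS = {"", "na", "nan"}


class SchemaError(ValueError):
    """A required column is absent or the file cannot be interpreted."""


class ValidationError(ValueError):
    """A cell violates a trait-table invariant."""


@dataclass
class TraitTable:
    """Species x trait table with an explicit missingness mask.

    ``data`` holds one row per species; ``mask`` is boolean, aligned with
    ``data``, True where a value is missing. Metadata columns (taxonomy,
    flexibility flag) are never masked.
    """

    data: pd.DataFrame
    mask: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TraitTable":
        df = df.copy().reset_index(drop=True)
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        missing += [
            c for c in ("body_mass_g", "litter_size", "foraging_stratum", "habitat_breadth")
            if c not in df.columns
        ]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        if not cls._diet_columns_of(df):
            raise SchemaError("no diet_<category> columns found")
        maskable = cls._maskable_columns_of(df)
        mask = df[maskable].isna()
        return cls(data=df, mask=mask)

    @staticmethod
    def _diet_columns_of(df: pd.DataFrame) -> list[str]:
        return [c for c in df.columns if c.startswith("diet_")]

    @staticmethod
    def _maskable_columns_of(df: pd.DataFrame) -> list[str]:
        return ["diel_niche", "body_mass_g", "litter_size", "foraging_stratum",
                "habitat_breadth"] + TraitTable._diet_columns_of(df)

    # -- views ---------------------------------------------------------

    @property
    def species(self) -> pd.Index:
        return pd.Index(self.data["species_id"])

    @property
    def diet_columns(self) -> list[str]:
        return self._diet_columns_of(self.data)

    @property
    def n_species(self) -> int:
        return len(self.data)

    def diet_matrix(self) -> pd.DataFrame:
        """The n x 10 semi-quantitative diet table, indexed by species."""
        out = self.data[self.diet_columns].copy()
        out.index = self.species
        return out

    def complete_rows(self) -> pd.Series:
        """Boolean per species: no masked cell anywhere."""
        return ~self.mask.any(axis=1)

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        df = self.data
        dup = df["species_id"][df["species_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate species_id: {sorted(set(dup))}")
        bad_niche = df["diel_niche"].dropna()[
            ~df["diel_niche"].dropna().isin(DIEL_NICHES)
        ]
        if len(bad_niche):
            raise ValidationError(f"unknown diel_niche values: {sorted(set(bad_niche))}")
        for col, check, what in (
            ("body_mass_g", lambda s: s <= 0, "non-positive body mass"),
            ("litter_size", lambda s: s <= 0, "non-positive litter size"),
            ("habitat_breadth", lambda s: s < 1, "habitat breadth below 1"),
        ):
            vals = pd.to_numeric(df[col], errors="coerce")
            flag = check(vals) & vals.notna()
            bad = df.index[flag.to_numpy(bool)]
            if len(bad):
                rows = ", ".join(str(df.loc[i, "species_id"]) for i in bad[:5])
                raise ValidationError(f"{what} for species: {rows}")
        strat = pd.to_numeric(df["foraging_stratum"], errors="coerce").dropna()
        bad = strat[~strat.isin([1, 2, 3, 4])]
        if len(bad):
            raise ValidationError(
                f"foraging_stratum outside 1..4 at rows {list(bad.index[:5])}"
            )
        diet = df[self.diet_columns].apply(pd.to_numeric, errors="coerce")
        if (diet.to_numpy() < 0).any():
            raise ValidationError("negative diet category score")


def read_trait_table(path) -> TraitTable:
    """Read a trait CSV (UTF-8, comma, header) into a validated TraitTable.

    Empty cells and the tokens NA / NaN (case-insensitive) are treated as
    missing and recorded in the mask.
    """
    df = pd.read_csv(
        path,
        na_values=sorted({t.upper() for t in _NA_TOKENS} | {"NA", "NaN", "na", "nan"}),
        keep_default_na=False,
        skipinitialspace=True,
    )
    df.columns = [c.strip() for c in df.columns]
    for col in df.columns:
        if df[col].dtype == object:
            stripped = df[col].str.strip()
            df[col] = stripped.mask(stripped.str.lower().isin(_NA_TOKENS))
    if "diel_flexible" in df.columns:
        df["diel_flexible"] = (
            df["diel_flexible"].astype(str).str.strip().str.lower()
            .map({"true": True, "false": False, "1": True, "0": False,
                  "yes": True, "no": False})
        )
    numeric = ["body_mass_g", "litter_size", "foraging_stratum", "habitat_breadth"]
    numeric += [c for c in df.columns if c.startswith("diet_")]
    for col in numeric:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return TraitTable.from_dataframe(df)


def write_trait_table(table: TraitTable, path) -> None:
    """Write the table back to CSV; masked cells are emitted as empty."""
    df = table.data.copy()
    for col in table.mask.columns:
        df.loc[table.mask[col].to_numpy(), col] = np.nan
    df.to_csv(path, index=False, na_rep="")


def trait_table_csv(table: TraitTable) -> str:
    buf = io.StringIO()
    write_trait_table(table, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    """z-transform using sample SD (n-1); NaNs pass through untouched."""
    obs = x[~np.isnan(x)]
    sd = obs.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValidationError("cannot standardise a zero-variance column")
    return (x - obs.mean()) / sd


def transform_standardise(
    table: TraitTable, diet_trait: pd.Series
) -> pd.DataFrame:
    """Five transformed, z-scored traits per species.

    body mass and litter size are log10-transformed, habitat breadth is
    square-root transformed, foraging stratum enters as its ordinal code and
    the diet trait as supplied; every column is then centred to zero mean
    and scaled to unit sample SD over its observed cells. Missing cells stay
    NaN (transforms precede imputation).
    """
    diet = diet_trait.reindex(table.species)
    if diet.isna().all():
        raise ValidationError("diet_trait does not align with the table's species")
    df = table.data
    raw = pd.DataFrame(
        {
            "body_mass": np.log10(df["body_mass_g"].to_numpy(float)),
            "litter_size": np.log10(df["litter_size"].to_numpy(float)),
            "diet": diet.to_numpy(float),
            "foraging_stratum": df["foraging_stratum"].to_numpy(float),
            "habitat_breadth": np.sqrt(df["habitat_breadth"].to_numpy(float)),
        },
        index=df.index,
    )
    return raw.apply(lambda c: _zscore(c.to_numpy(float)), raw=False)


# ---------------------------------------------------------------------------
# collinearity / correlation diagnostics
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    correlations: pd.DataFrame  # 5x5 Pearson r, unit diagonal
    vif: pd.Series              # one VIF per trait
    n_complete: int


def diagnostics(transformed: pd.DataFrame) -> DiagnosticsReport:
    """Pairwise Pearson correlations and variance inflation factors.

    Computed on complete cases only. VIF_j = 1/(1 - R^2_j) from regressing
    trait j on the other traits; equivalently the diagonal of the inverse
    correlation matrix. Perfect collinearity yields VIF = inf.
    """
    cc = transformed.dropna()
    if len(cc) < 3:
        raise ValidationError("need at least 3 complete rows for diagnostics")
    X = cc.to_numpy(float)
    corr = np.corrcoef(X, rowvar=False)
    vifs = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(X)), others])
        beta, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
        resid = X[:, j] - A @ beta
        ss_res = float(resid @ resid)
        y = X[:, j] - X[:, j].mean()
        ss_tot = float(y @ y)
        r2 = 1.0 - ss_res / ss_tot
        vifs.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    cols = list(transformed.columns)
    return DiagnosticsReport(
        correlations=pd.DataFrame(corr, index=cols, columns=cols),
        vif=pd.Series(vifs, index=cols),
        n_complete=len(cc),
    )
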