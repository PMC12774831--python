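"""Declarative feature specification and combinatorial expansion.

A :class:`FeatureSpec` declares base annotations (numeric, categorical or
indicator, each with an imputation default) and combination rules that cross a
categorical annotation with one or two numeric annotations, emitting one
product column per category.  The shipped default spec expands to 691 columns,
581 of them combinatorial, mirroring a CADD-style feature layout for a fly
genome (consequence classes crossed with conservation and positional scores).

Expansion and scaling are exposed as scikit-learn transformers
(:class:`FeatureExpander`, :class:`SdScaler`) so the whole model composes with
sklearn pipelines; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .annotate import (
    AMINO_ACIDS,
    CONSEQUENCE_PRIORITY,
    INDICATOR_TRACK_NAMES,
    PER_BASE_TRACK_NAMES,
)
from .io import spec_checksum

SCALED_FLAG = "snvcadd_scaled"


@dataclass
class BaseAnnotation:
    name: str
    kind: str                       # "numeric" | "categorical" | "indicator"
    categories: list[str] = field(default_factory=list)
    default: object = None          # imputation default; None => all-zero row
    missing_indicator: bool = False # numeric only: add a 0/1 missingness column
    other_bucket: str | None = None # categorical: bucket for unknown categories

    def n_columns(self) -> int:
        if self.kind == "categorical":
            return len(self.categories)
        if self.kind == "numeric":
            return 1 + int(self.missing_indicator)
        return 1


@dataclass
class CombinationRule:
    categorical: str
    numerics: list[str]             # one or two numeric base names


class FeatureSpec:
    """Base annotations plus combination rules, with a stable column order."""

    def __init__(self, bases: list[BaseAnnotation], combinations: list[CombinationRule]):
        self.bases = bases
        self.combinations = combinations
        self._by_name = {b.name: b for b in bases}
        if len(self._by_name) != len(bases):
            raise ValueError("duplicate base annotation names")
        self.validate()

    def base(self, name: str) -> BaseAnnotation:
        return self._by_name[name]

    def validate(self) -> None:
        for rule in self.combinations:
            cat = self._by_name.get(rule.categorical)
            if cat is None or cat.kind != "categorical":
                raise ValueError(
                    f"combination references unknown/non-categorical base "
                    f"{rule.categorical!r}"
                )
            if not 1 <= len(rule.numerics) <= 2:
                raise ValueError("combination rules take one or two numerics")
            for num in rule.numerics:
                base = self._by_name.get(num)
                if base is None or base.kind != "numeric":
                    raise ValueError(
                        f"combination references unknown/non-numeric base {num!r}"
                    )
        names = self.column_names()
        if len(names) != len(set(names)):
            dupes = pd.Series(names)
            raise ValueError(
                f"expanded column names not unique: "
                f"{sorted(dupes[dupes.duplicated()].unique())}"
            )

    # -- column layout -----------------------------------------------------

    def _cat_label(self, base: BaseAnnotation, category: str) -> str:
        # consequence categories are unique tokens and stay bare in composite
        # names (the "SN_relCDSpos_PhyloP" naming convention)
        if base.name == "Consequence":
            return category
        return f"{base.name}_{category}"

    def column_names(self) -> list[str]:
        cols: list[str] = []
        for base in self.bases:
            if base.kind == "categorical":
                cols.extend(f"{base.name}_{c}" for c in base.categories)
            else:
                cols.append(base.name)
                if base.kind == "numeric" and base.missing_indicator:
                    cols.append(f"{base.name}_missing")
        cols.extend(self.combination_column_names())
        return cols

    def combination_column_names(self) -> list[str]:
        cols = []
        for rule in self.combinations:
            base = self._by_name[rule.categorical]
            suffix = "_".join(rule.numerics)
            cols.extend(
                f"{self._cat_label(base, c)}_{suffix}" for c in base.categories
            )
        return cols

    def n_columns(self) -> int:
        return len(self.column_names())

    def n_combinatorial(self) -> int:
        return len(self.combination_column_names())

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "bases": [asdict(b) for b in self.bases],
            "combinations": [asdict(c) for c in self.combinations],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        return cls(
            bases=[BaseAnnotation(**b) for b in d["bases"]],
            combinations=[CombinationRule(**c) for c in d["combinations"]],
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def checksum(self) -> str:
        return spec_checksum(json.dumps(self.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# The shipped default spec (691 columns, 581 combinatorial, 38 annotations)
# ---------------------------------------------------------------------------

_NUMERIC_BASES = [
    "CDSpos", "relCDSpos", "protPos", "relProtPos", "Grantham",
    *PER_BASE_TRACK_NAMES, "ReMapDensity", "CDSdist", "GC",
]
_CONSERVATION = ["PhyloP", "PhyloP124", "PhyloP_all", "PhastCons",
                 "PhastCons124", "GerpRS_all", "GERPN_all"]
_CHROMATIN_STATES = [str(i) for i in range(1, 10)]  # 9-state chromatin model


def default_feature_spec() -> FeatureSpec:
    """The shipped feature layout: 38 base annotations expanding to 691
    columns of which 581 are combinatorial."""
    bases: list[BaseAnnotation] = [
        BaseAnnotation("Consequence", "categorical",
                       categories=list(CONSEQUENCE_PRIORITY), default="IG"),
        BaseAnnotation("oAA", "categorical", categories=list(AMINO_ACIDS)),
        BaseAnnotation("nAA", "categorical", categories=list(AMINO_ACIDS)),
        BaseAnnotation("ChromatinBG3", "categorical",
                       categories=list(_CHROMATIN_STATES), default="9"),
        BaseAnnotation("ChromatinS2", "categorical",
                       categories=list(_CHROMATIN_STATES), default="9"),
    ]
    for name in _NUMERIC_BASES:
        bases.append(
            BaseAnnotation(
                name, "numeric", default=0.0,
                missing_indicator=name in ("Grantham", "CDSpos", "protPos"),
            )
        )
    for name in INDICATOR_TRACK_NAMES + ["CDS"]:
        bases.append(BaseAnnotation(name, "indicator", default=0))

    combos: list[CombinationRule] = []
    for num in _NUMERIC_BASES:
        combos.append(CombinationRule("Consequence", [num]))
    for cons in _CONSERVATION:
        combos.append(CombinationRule("Consequence", ["relCDSpos", cons]))
    combos.append(CombinationRule("Consequence", ["relProtPos", "PhyloP"]))
    combos.append(CombinationRule("Consequence", ["relProtPos", "PhastCons"]))
    combos.append(CombinationRule("Consequence", ["Grantham", "PhyloP"]))
    combos.append(CombinationRule("Consequence", ["CDSdist", "PhyloP"]))
    for aa_col in ("oAA", "nAA"):
        combos.append(CombinationRule(aa_col, ["Grantham"]))
        combos.append(CombinationRule(aa_col, ["relProtPos"]))
    for chrom_col in ("ChromatinBG3", "ChromatinS2"):
        combos.append(CombinationRule(chrom_col, ["PhyloP"]))
        combos.append(CombinationRule(chrom_col, ["PhastCons"]))
        combos.append(CombinationRule(chrom_col, ["GC"]))
    combos.append(CombinationRule("ChromatinBG3", ["ReMapDensity"]))
    return FeatureSpec(bases, combos)


# ---------------------------------------------------------------------------
# Expansion
# ---------------------------------------------------------------------------

class FeatureExpander(TransformerMixin, BaseEstimator):
    """Expand a base-annotation table into the numeric feature matrix.

    Stateless apart from the spec; ``fit`` only validates.  Missing numerics
    take the declared default (plus a missingness column when declared);
    missing categoricals take the default category, or an all-zero one-hot row
    when no default is declared; unknown categories map to the declared
    "other" bucket with a warning.
    """

    def __init__(self, spec: FeatureSpec | None = None):
        self.spec = spec

    def _spec(self) -> FeatureSpec:
        return self.spec if self.spec is not None else default_feature_spec()

    def fit(self, X: pd.DataFrame, y=None):
        spec = self._spec()
        spec.validate()
        missing = [b.name for b in spec.bases if b.name not in X.columns]
        if missing:
            raise KeyError(f"base annotation column(s) absent from input: {missing}")
        self.feature_names_out_ = spec.column_names()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        spec = self._spec()
        n = len(X)
        data: dict[str, np.ndarray] = {}
        onehots: dict[str, dict[str, np.ndarray]] = {}
        imputed: dict[str, np.ndarray] = {}

        for base in spec.bases:
            col = X[base.name]
            if base.kind == "numeric":
                vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
                missing = ~np.isfinite(vals)
                filled = np.where(missing, float(base.default or 0.0), vals)
                data[base.name] = filled
                imputed[base.name] = filled
                if base.missing_indicator:
                    data[f"{base.name}_missing"] = missing.astype(float)
            elif base.kind == "indicator":
                vals = col.to_numpy()
                out = np.zeros(n)
                for i, v in enumerate(vals):
                    if v is None or (isinstance(v, float) and np.isnan(v)):
                        out[i] = float(base.default or 0)
                    else:
                        out[i] = float(bool(v))
                data[base.name] = out
            else:  # categorical
                raw = col.to_numpy(dtype=object)
                cats = set(base.categories)
                mapped = np.empty(n, dtype=object)
                unknown: set[str] = set()
                for i, v in enumerate(raw):
                    if v is None or (isinstance(v, float) and np.isnan(v)):
                        mapped[i] = base.default  # may be None => all-zero
                    elif str(v) in cats:
                        mapped[i] = str(v)
                    elif base.other_bucket is not None:
                        mapped[i] = base.other_bucket
                        unknown.add(str(v))
                    else:
                        mapped[i] = None
                        unknown.add(str(v))
                if unknown:
                    warnings.warn(
                        f"{base.name}: unknown categor{'y' if len(unknown)==1 else 'ies'} "
                        f"{sorted(unknown)} mapped to "
                        f"{base.other_bucket or 'all-zero encoding'}"
                    )
                oh = {}
                for c in base.categories:
                    colvals = (mapped == c).astype(float)
                    data[f"{base.name}_{c}"] = colvals
                    oh[c] = colvals
                onehots[base.name] = oh

        for rule in spec.combinations:
            base = spec.base(rule.categorical)
            prod = np.ones(n)
            for num in rule.numerics:
                prod = prod * imputed[num]
            suffix = "_".join(rule.numerics)
            for c in base.categories:
                name = f"{spec._cat_label(base, c)}_{suffix}"
                data[name] = onehots[rule.categorical][c] * prod

        out = pd.DataFrame(data, index=X.index)[spec.column_names()]
        out.attrs[SCALED_FLAG] = False
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self._spec().column_names(), dtype=object)


def expand_features(annotated: pd.DataFrame, spec: FeatureSpec | None = None) -> pd.DataFrame:
    return FeatureExpander(spec).fit(annotated).transform(annotated)


# ---------------------------------------------------------------------------
# SD scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingParams:
    sds: dict[str, float]           # per retained column, population SD
    dropped: list[str]              # constant columns removed from the model

    def to_dict(self) -> dict:
        return {"sds": self.sds, "dropped": self.dropped}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(sds={k: float(v) for k, v in d["sds"].items()},
                   dropped=list(d["dropped"]))


class SdScaler(TransformerMixin, BaseEstimator):
    """Divide every column by its training-set population standard deviation.

    No centering; constant columns are dropped from the model's view.  A
    transformed frame is flagged so it cannot be scaled a second time.
    """

    def fit(self, X: pd.DataFrame, y=None):
        if len(X) < 2:
            raise ValueError("scaling needs at least 2 rows")
        sds = X.std(axis=0, ddof=0)
        self.dropped_ = list(sds.index[sds == 0])
        kept = sds[sds > 0]
        self.sds_ = kept
        self.feature_names_in_ = list(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "sds_")
        if X.attrs.get(SCALED_FLAG):
            raise ValueError("matrix is already scaled")
        missing = [c for c in self.sds_.index if c not in X.columns]
        if missing:
            raise KeyError(f"column(s) absent from input: {missing}")
        unseen = [c for c in X.columns if c not in self.feature_names_in_]
        if unseen:
            raise KeyError(f"unseen column(s): {unseen}")
        out = X[self.sds_.index] / self.sds_
        out.attrs[SCALED_FLAG] = True
        return out

    def params(self) -> ScalingParams:
        check_is_fitted(self, "sds_")
        return ScalingParams(sds={k: float(v) for k, v in self.sds_.items()},
                             dropped=list(self.dropped_))

    @classmethod
    def from_params(cls, params: ScalingParams) -> "SdScaler":
        scaler = cls()
        scaler.sds_ = pd.Series(params.sds)
        scaler.dropped_ = list(params.dropped)
        scaler.feature_names_in_ = list(params.sds) + list(params.dropped)
        return scaler


def fit_scaler(matrix: pd.DataFrame) -> SdScaler:
    return SdScaler().fit(matrix)


def apply_scaler(matrix: pd.DataFrame, scaler: SdScaler) -> pd.DataFrame:
    return scaler.transform(matrix)
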