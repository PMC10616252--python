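"""One-hot encoding of host variables and microbial/host feature fusion.

Continuous host variables are first discretized — age into Young (<=35),
Middle (36-59) and Old (>=60); BMI into Low (<18.5), Middle (18.5-23.9)
and High (>=24) — then every variable is encoded as a binary indicator
vector with exactly one active bit: Male -> (1, 0), Female -> (0, 1),
age 36 -> (0, 1, 0), and so on.  Encoded host columns are concatenated
after the genus columns and each row is L2-normalized to unit norm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import normalize

logger = logging.getLogger(__name__)

# continuous reading of the printed bins: gapless partition of the line
AGE_BINS = ((-np.inf, 35.0, "Young"), (35.0, 60.0, "Middle"),
            (60.0, np.inf, "Old"))          # Young <=35, Middle 36-59, Old >=60
BMI_BINS = ((-np.inf, 18.5, "Low"), (18.5, 24.0, "Middle"),
            (24.0, np.inf, "High"))         # Low <18.5, Middle 18.5-23.9, High >=24


def bin_age(age: float) -> str:
    if age <= 0:
        raise ValueError(f"age must be positive, got {age}")
    if age <= 35:
        return "Young"
    if age < 60:
        return "Middle"
    return "Old"


def bin_bmi(bmi: float) -> str:
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    if bmi < 18.5:
        return "Low"
    if bmi < 24.0:
        return "Middle"
    return "High"


@dataclass
class EncodingSpec:
    """Category lists and bin edges for the host-variable one-hot scheme.

    Column order is fixed by the order of the dict: each variable
    occupies ``len(categories)`` adjacent binary columns named
    ``<variable>_<category>``.
    """

    gender: list[str] = field(default_factory=lambda: ["Male", "Female"])
    age_groups: list[str] = field(default_factory=lambda: ["Young", "Middle", "Old"])
    bmi_groups: list[str] = field(default_factory=lambda: ["Low", "Middle", "High"])
    probiotics: list[str] = field(default_factory=lambda: ["yes", "no"])
    health_status: list[str] = field(default_factory=lambda: ["healthy", "unhealthy"])

    def variables(self) -> dict[str, list[str]]:
        return {"gender": self.gender, "age": self.age_groups,
                "bmi": self.bmi_groups, "probiotics": self.probiotics,
                "health_status": self.health_status}

    def column_names(self) -> list[str]:
        return [f"{var}_{cat}" for var, cats in self.variables().items()
                for cat in cats]

    def n_columns(self) -> int:
        return len(self.column_names())

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"gender": self.gender, "age_groups": self.age_groups,
                            "bmi_groups": self.bmi_groups,
                            "probiotics": self.probiotics,
                            "health_status": self.health_status}, fh,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EncodingSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class HostOneHotEncoder(BaseEstimator, TransformerMixin):
    """Transformer mapping a host-metadata frame to the fixed one-hot layout.

    The layout is given by an :class:`EncodingSpec` (default: 12 columns —
    2 gender + 3 age + 3 BMI + 2 probiotics + 2 health status).  ``fit``
    validates that every observed category is representable (extending
    ``health_status`` with unseen categories when ``extend_health=True``);
    ``transform`` emits the binary matrix with exactly one active bit per
    variable per sample.
    """

    def __init__(self, spec: EncodingSpec | None = None,
                 extend_health: bool = False):
        self.spec = spec
        self.extend_health = extend_health

    def fit(self, meta: pd.DataFrame, y=None):
        spec = self.spec if self.spec is not None else EncodingSpec()
        if self.extend_health:
            extra = sorted(set(meta["health_status"].astype(str))
                           - set(spec.health_status))
            if extra:
                spec = EncodingSpec(
                    gender=spec.gender, age_groups=spec.age_groups,
                    bmi_groups=spec.bmi_groups, probiotics=spec.probiotics,
                    health_status=spec.health_status + extra)
        self.spec_ = spec
        self.columns_ = spec.column_names()
        return self

    def transform(self, meta: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "spec_"):
            raise RuntimeError("HostOneHotEncoder is not fitted")
        spec = self.spec_
        out = pd.DataFrame(0.0, index=meta.index, columns=self.columns_)
        for sample, row in meta.iterrows():
            cats = {
                "gender": str(row["gender"]),
                "age": bin_age(float(row["age"])),
                "bmi": bin_bmi(float(row["bmi"])),
                "probiotics": str(row["probiotics"]),
                "health_status": str(row["health_status"]),
            }
            for var, cat in cats.items():
                allowed = spec.variables()[var]
                if cat not in allowed:
                    raise ValueError(
                        f"sample {sample!r}: {var} value {cat!r} not in "
                        f"categories {allowed}")
                out.loc[sample, f"{var}_{cat}"] = 1.0
        return out

    def get_feature_names_out(self, input_features=None):  # sklearn API
        return np.asarray(self.columns_)


def one_hot_encode(meta: pd.DataFrame,
                   spec: EncodingSpec | None = None) -> pd.DataFrame:
    """Functional form of :class:`HostOneHotEncoder` (fit+transform)."""
    return HostOneHotEncoder(spec=spec).fit(meta).transform(meta)


def fuse_and_normalize(microbial: pd.DataFrame,
                       encoded: pd.DataFrame) -> pd.DataFrame:
    """Concatenate genus features with encoded host features and
    L2-normalize each row to unit norm.

    Sample order must match exactly.  All-zero rows are left as zeros and
    flagged with a warning (unit norm is unattainable for them).
    """
    if list(microbial.index) != list(encoded.index):
        raise ValueError("sample order mismatch between microbial and "
                         "encoded feature matrices")
    fused = pd.concat([microbial, encoded], axis=1)
    norms = np.linalg.norm(fused.values, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("fuse_and_normalize: %d all-zero rows left "
                       "unnormalized", int(zero.sum()))
    vals = normalize(fused.values, norm="l2")  # leaves zero rows at zero
    return pd.DataFrame(vals, index=fused.index, columns=fused.columns)
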