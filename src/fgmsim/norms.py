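"""Logistic model of the probability that a woman's daughter is cut.

The model regresses the daughter-cut indicator on the mother's own support
for FGM, the average support in her community, and individual controls
(age, wealth quintile, education, urban residence, religion).  Community
support is the simple community mean of the individual support indicator,
including the woman herself by default (leave-one-out available as an
option).  Controls are coded as: age linear, wealth and education
ordinal-as-numeric, urban binary, religion one-hot against the largest
category.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .errors import SeparationError, ValidationError

#: microdata columns required for fitting/prediction
MICRODATA_COLUMNS = (
    "woman_id",
    "community_id",
    "age",
    "wealth",
    "education",
    "urban",
    "religion",
    "supports_fgm",
    "daughter_cut",
)

NUMERIC_CONTROLS = ("age", "wealth", "education", "urban")


def validate_microdata(df: pd.DataFrame, *, require_outcome: bool = True) -> None:
    """Check the microdata frame against the documented schema.

    Support may be fractional (in [0, 1]) after an expectation-mode attitude
    shift; ages must lie in the surveyed range 15-49; no missing values.
    """
    required = set(MICRODATA_COLUMNS) - ({"daughter_cut"} if not require_outcome else set())
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"microdata missing columns: {sorted(missing)}")
    if df[sorted(required)].isna().any().any():
        raise ValidationError("microdata contains missing values")
    if not df["age"].between(15, 49).all():
        raise ValidationError("age: values must lie in 15-49")
    s = df["supports_fgm"].to_numpy(dtype=float)
    if ((s < 0) | (s > 1)).any():
        raise ValidationError("supports_fgm: values must lie in [0, 1]")


def community_support(df: pd.DataFrame, *, leave_one_out: bool = False) -> pd.Series:
    """Per-woman average community support, aligned to ``df``.

    The default is the simple community mean of ``supports_fgm`` including
    the woman herself; ``leave_one_out=True`` excludes her.
    """
    grp = df.groupby("community_id")["supports_fgm"]
    mean = grp.transform("mean")
    if not leave_one_out:
        return mean.rename("community_support")
    n = grp.transform("size")
    if (n < 2).any():
        raise ValidationError("community_id: leave-one-out needs >= 2 women per community")
    loo = (mean * n - df["supports_fgm"]) / (n - 1)
    return loo.rename("community_support")


@dataclass
class CutProbabilityModel:
    """Fitted (or assumed) coefficients of the daughter-cut logistic model.

    ``coef_controls`` maps control names to coefficients; religion levels use
    keys of the form ``"religion:<level>"`` and the reference level carries
    no coefficient.
    """

    intercept: float
    coef_individual_support: float
    coef_community_support: float
    coef_controls: Mapping[str, float] = field(default_factory=dict)
    religion_reference: str | None = None
    stderr: Mapping[str, float] | None = None
    conf_int: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        vals = [self.intercept, self.coef_individual_support, self.coef_community_support,
                *self.coef_controls.values()]
        if not np.all(np.isfinite(vals)):
            raise ValidationError("coefficients must all be finite")

    @property
    def religion_levels(self) -> list[str]:
        levels = [k.split(":", 1)[1] for k in self.coef_controls if k.startswith("religion:")]
        if self.religion_reference is not None:
            levels.append(self.religion_reference)
        return sorted(levels)

    # -- linear predictor -------------------------------------------------

    def linear_predictor(
        self,
        supports_fgm: np.ndarray | float,
        community_support: np.ndarray | float,
        controls: pd.DataFrame | Mapping,
    ) -> np.ndarray | float:
        if isinstance(controls, Mapping):
            controls = pd.DataFrame({k: [v] for k, v in controls.items()})
            scalar = True
        else:
            scalar = False
        eta = (
            self.intercept
            + self.coef_individual_support * np.asarray(supports_fgm, dtype=float)
            + self.coef_community_support * np.asarray(community_support, dtype=float)
        )
        for name in NUMERIC_CONTROLS:
            coef = self.coef_controls.get(name, 0.0)
            if coef and name not in controls:
                raise ValidationError(f"controls missing field: {name}")
            if name in controls:
                eta = eta + coef * controls[name].to_numpy(dtype=float)
        if "religion" in controls:
            rel = controls["religion"].astype(str)
            known = set(self.religion_levels)
            if known:
                unknown = set(rel.unique()) - known
                if unknown:
                    raise ValidationError(f"religion: unknown level(s) {sorted(unknown)}")
            for key, coef in self.coef_controls.items():
                if key.startswith("religion:"):
                    eta = eta + coef * (rel == key.split(":", 1)[1]).to_numpy(dtype=float)
        eta = np.asarray(eta, dtype=float)
        return float(eta[0]) if scalar else eta

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "intercept": self.intercept,
            "coef_individual_support": self.coef_individual_support,
            "coef_community_support": self.coef_community_support,
            "coef_controls": dict(self.coef_controls),
            "religion_reference": self.religion_reference,
            "stderr": dict(self.stderr) if self.stderr else None,
            "conf_int": {k: list(v) for k, v in self.conf_int.items()} if self.conf_int else None,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CutProbabilityModel":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            coef_individual_support=d["coef_individual_support"],
            coef_community_support=d["coef_community_support"],
            coef_controls=d.get("coef_controls", {}),
            religion_reference=d.get("religion_reference"),
            stderr=d.get("stderr"),
            conf_int={k: tuple(v) for k, v in d["conf_int"].items()} if d.get("conf_int") else None,
        )


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _design_matrix(df: pd.DataFrame, religion_levels: list[str], reference: str) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    cols.append(df["supports_fgm"].to_numpy(dtype=float))
    names.append("supports_fgm")
    cols.append(df["community_support"].to_numpy(dtype=float))
    names.append("community_support")
    for c in NUMERIC_CONTROLS:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
    for lvl in religion_levels:
        if lvl == reference:
            continue
        cols.append((df["religion"].astype(str) == lvl).to_numpy(dtype=float))
        names.append(f"religion:{lvl}")
    return np.column_stack(cols), names


def fit(
    data: pd.DataFrame,
    *,
    leave_one_out: bool = False,
    weight_col: str | None = None,
    regularized: bool = False,
) -> CutProbabilityModel:
    """Maximum-likelihood logistic fit of the daughter-cut model.

    Community support is computed from the data itself.  If ``weight_col``
    names a column it is used as frequency weights.  Perfect separation
    raises :class:`SeparationError`; pass ``regularized=True`` to fall back
    to an L1-penalized fit in that situation.
    """
    validate_microdata(data)
    y = data["daughter_cut"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("daughter_cut: both outcome classes must be present")
    df = data.copy()
    df["community_support"] = community_support(df, leave_one_out=leave_one_out)

    religion_levels = sorted(df["religion"].astype(str).unique())
    reference = df["religion"].astype(str).value_counts().idxmax()
    X, names = _design_matrix(df, religion_levels, reference)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            if weight_col is not None:
                res = sm.GLM(y, X, family=sm.families.Binomial(),
                             freq_weights=df[weight_col].to_numpy(dtype=float)).fit()
            elif regularized:
                res = sm.Logit(y, X).fit_regularized(alpha=1.0, disp=0)
            else:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(
            "perfect separation in logistic fit; re-fit with regularized=True"
        ) from exc
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(params)) or (not regularized and not np.all(np.isfinite(bse))):
        raise SeparationError(
            "non-finite estimates in logistic fit; re-fit with regularized=True"
        )
    ci = np.asarray(res.conf_int())
    coef = dict(zip(names, params))
    controls = {k: v for k, v in coef.items()
                if k not in ("intercept", "supports_fgm", "community_support")}
    return CutProbabilityModel(
        intercept=coef["intercept"],
        coef_individual_support=coef["supports_fgm"],
        coef_community_support=coef["community_support"],
        coef_controls=controls,
        religion_reference=reference,
        stderr=dict(zip(names, bse)),
        conf_int={n: (float(lo), float(hi)) for n, (lo, hi) in zip(names, ci)},
    )


def predict(
    model: CutProbabilityModel,
    supports_fgm: float,
    community_support: float,
    controls: Mapping,
) -> float:
    """Probability that the daughter is cut, for one woman."""
    if not 0 <= supports_fgm <= 1 or not 0 <= community_support <= 1:
        raise ValidationError("supports_fgm/community_support must lie in [0, 1]")
    return float(expit(model.linear_predictor(supports_fgm, community_support, controls)))


def predict_frame(model: CutProbabilityModel, df: pd.DataFrame) -> np.ndarray:
    """Vectorized predictions for a microdata frame.

    Uses an existing ``community_support`` column, or computes the community
    mean of ``supports_fgm`` when absent.
    """
    comm = (
        df["community_support"]
        if "community_support" in df.columns
        else community_support(df)
    )
    eta = model.linear_predictor(
        df["supports_fgm"].to_numpy(dtype=float), comm.to_numpy(dtype=float), df
    )
    return expit(eta)
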