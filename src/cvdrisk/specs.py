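"""Risk-model specification schema, loading, validation and builtins.

A :class:`ModelSpec` is a complete, serializable description of one
sex-specific cardiovascular-mortality risk equation.  Two families are
supported:

``cox_form``
    Proportional-hazards style equations (Framingham, Pooled Cohort
    Equations, CN-ICVD): absolute risk over horizon ``h`` is

        risk = 1 - S0(h) ** exp(L - Lbar)

    where ``L`` is the linear predictor built from :class:`TermSpec` terms,
    ``Lbar`` the population mean of ``L`` ("Mean (Coefficient x Value)") and
    ``S0(h)`` the baseline survival at the mean linear predictor.

``weibull_score``
    SCORE-style two-cause Weibull equations parameterized by
    :class:`WeibullCauseParams` (per-cause log-scale intercept alpha, shape
    exponent p, and coefficients on cholesterol, SBP and smoking).

Spec files are the single source of model math; the scoring engine contains
no hard-coded coefficients.  The recalibrated parameter sets shipped under
``cvdrisk/data`` cover the general/simplified Framingham, CN-ICVD and both
PCE equations per sex; SCORE specs ship with clearly labelled synthetic
placeholder Weibull parameters that users replace with licensed values.

Schema version: 1 (JSON/YAML)::

    {"model_id": ..., "sex": "male"|"female", "family": "cox_form",
     "native_horizon": 5, "baseline_survival": {"5": 0.99...},
     "mean_lp": ..., "terms": [{"covariate": ..., "transform": ...,
     "coefficient": ..., "condition": {...}?, "bands": [...]?,
     "factors": [...]?}], "thresholds": [...], "category_labels": [...],
     "units": {...}, "diabetes_multiplier": {"male": 3, "female": 5}?,
     "weibull": {...}?, "metadata": {...}}
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

SCHEMA_VERSION = 1

DATA_DIR = Path(__file__).parent / "data"


class ModelSpecError(ValueError):
    """Raised when a model-specification file violates the schema."""


class Condition(BaseModel):
    """Predicate selecting when a term applies (e.g. BP-treated only)."""

    model_config = ConfigDict(extra="forbid")

    covariate: str
    equals: bool | float | str


class Band(BaseModel):
    """One half-open category band ``[lo, hi)`` with its coefficient."""

    model_config = ConfigDict(extra="forbid")

    lo: Optional[float] = None  # None = -inf
    hi: Optional[float] = None  # None = +inf
    coefficient: float


class Factor(BaseModel):
    """One factor of a product term (e.g. ``ln age`` in ``ln age x ln TC``)."""

    model_config = ConfigDict(extra="forbid")

    covariate: str
    transform: Literal["identity", "log"]


class TermSpec(BaseModel):
    """A single additive term of a ``cox_form`` linear predictor."""

    model_config = ConfigDict(extra="forbid")

    covariate: Optional[str] = None
    transform: Literal["identity", "log", "band", "product"]
    coefficient: Optional[float] = None
    condition: Optional[Condition] = None
    bands: Optional[list[Band]] = None
    factors: Optional[list[Factor]] = None
    label: Optional[str] = None

    @model_validator(mode="after")
    def _check_shape(self) -> "TermSpec":
        if self.transform == "band":
            if not self.bands:
                raise ValueError("band term requires 'bands'")
            if self.covariate is None:
                raise ValueError("band term requires 'covariate'")
            self._check_partition()
        elif self.transform == "product":
            if not self.factors or len(self.factors) != 2:
                raise ValueError("product term requires exactly 2 'factors'")
            if self.coefficient is None:
                raise ValueError("product term requires 'coefficient'")
        else:
            if self.covariate is None:
                raise ValueError(f"{self.transform} term requires 'covariate'")
            if self.coefficient is None:
                raise ValueError(f"{self.transform} term requires 'coefficient'")
        return self

    def _check_partition(self) -> None:
        """Bands must partition the real line with contiguous [lo, hi)."""
        bands = self.bands
        if bands[0].lo is not None:
            raise ValueError(f"bands for {self.covariate!r} must start open-ended (lo=null)")
        if bands[-1].hi is not None:
            raise ValueError(f"bands for {self.covariate!r} must end open-ended (hi=null)")
        for a, b in zip(bands, bands[1:]):
            if a.hi is None or b.lo is None or a.hi != b.lo:
                raise ValueError(
                    f"bands for {self.covariate!r} do not partition the line: "
                    f"[{a.lo}, {a.hi}) followed by [{b.lo}, {b.hi})"
                )


class WeibullCause(BaseModel):
    """Weibull parameters for one cause of death (CHD or non-CHD CVD)."""

    model_config = ConfigDict(extra="forbid")

    alpha: float
    p: float = Field(gt=0)
    beta_chol: float
    beta_sbp: float
    beta_smoker: float


class WeibullCauseParams(BaseModel):
    """Two-cause Weibull parameter set of a SCORE-family equation."""

    model_config = ConfigDict(extra="forbid")

    chd: WeibullCause
    non_chd: WeibullCause
    region: Literal["high", "low"]


class ModelSpec(BaseModel):
    """Complete description of one sex-specific risk equation."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = SCHEMA_VERSION
    model_id: str
    sex: Literal["male", "female"]
    family: Literal["cox_form", "weibull_score"]
    native_horizon: float = Field(gt=0)
    baseline_survival: dict[float, float] = Field(default_factory=dict)
    mean_lp: Optional[float] = None
    terms: Optional[list[TermSpec]] = None
    weibull: Optional[WeibullCauseParams] = None
    thresholds: list[float] = Field(default_factory=list)
    category_labels: Optional[list[str]] = None
    units: dict[str, str] = Field(default_factory=dict)
    diabetes_multiplier: Optional[dict[str, float]] = None
    metadata: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "ModelSpec":
        for h, s in self.baseline_survival.items():
            if not (0.0 < s < 1.0):
                raise ValueError(f"baseline_survival[{h}] = {s} not strictly in (0, 1)")
            if h <= 0:
                raise ValueError(f"baseline_survival horizon {h} must be positive")
        if any(b >= a for a, b in zip(self.thresholds[1:], self.thresholds)):
            raise ValueError(f"thresholds {self.thresholds} must be strictly increasing")
        if self.category_labels is not None and len(self.category_labels) != len(self.thresholds) + 1:
            raise ValueError("category_labels must have len(thresholds) + 1 entries")
        if self.family == "cox_form":
            if self.mean_lp is None:
                raise ValueError("cox_form spec requires 'mean_lp'")
            if not self.terms:
                raise ValueError("cox_form spec requires at least one term")
            if not self.baseline_survival:
                raise ValueError("cox_form spec requires baseline_survival at >=1 horizon")
            if self.weibull is not None:
                raise ValueError("cox_form spec must not carry 'weibull' parameters")
        else:
            if self.weibull is None:
                raise ValueError("weibull_score spec requires 'weibull' parameters")
            if self.terms:
                raise ValueError("weibull_score spec must not carry 'terms'")
        return self

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        """Plain-dict form with canonical key ordering and string horizons."""
        d = self.model_dump(exclude_none=True)
        d["baseline_survival"] = {
            _fmt_horizon(h): s for h, s in sorted(self.baseline_survival.items())
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(self.to_json() + "\n")


def _fmt_horizon(h: float) -> str:
    return str(int(h)) if float(h).is_integer() else str(h)


def load_model_spec(path: str | Path) -> ModelSpec:
    """Load and validate a model specification from a JSON or YAML file.

    Raises
    ------
    ModelSpecError
        If the file does not parse or violates a schema invariant; the
        message names the offending field.
    FileNotFoundError
        If ``path`` does not exist.
    """
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix in (".yaml", ".yml"):
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ModelSpecError(f"{path}: cannot parse file: {exc}") from exc
    return model_spec_from_dict(raw, source=str(path))


def model_spec_from_dict(raw: dict, source: str = "<dict>") -> ModelSpec:
    """Validate a raw mapping as a :class:`ModelSpec`."""
    if not isinstance(raw, dict):
        raise ModelSpecError(f"{source}: expected a mapping at top level")
    raw = dict(raw)
    bs = raw.get("baseline_survival")
    if isinstance(bs, dict):
        try:
            raw["baseline_survival"] = {float(k): v for k, v in bs.items()}
        except (TypeError, ValueError) as exc:
            raise ModelSpecError(f"{source}: baseline_survival keys must be numeric: {exc}")
    try:
        return ModelSpec.model_validate(raw)
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        msgs = "; ".join(err["msg"] for err in exc.errors())
        raise ModelSpecError(f"{source}: invalid model spec (field(s): {fields}): {msgs}") from exc


def builtin_recalibrated_specs() -> dict[str, ModelSpec]:
    """All model specifications shipped with the package.

    Returns a mapping ``"<model_id>/<sex>" -> ModelSpec`` containing the ten
    recalibrated cox-form equations (general-FRS, simplified-FRS, CN-ICVD,
    PCE-white, PCE-AA; per sex) plus four SCORE weibull specs with synthetic
    placeholder parameters (``metadata.synthetic`` is true for those).
    """
    specs = {}
    for path in sorted(DATA_DIR.glob("*.json")):
        spec = load_model_spec(path)
        specs[f"{spec.model_id}/{spec.sex}"] = spec
    return specs
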