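"""Model inputs: typed parameter registry, strategies, and the OR→RR conversion.

Every quantity the decision model consumes — febrile-neutropenia (FN) risks,
G-CSF effectiveness relative risks, relative-dose-intensity (RDI) parameters,
utilities, unit costs and structural constants — lives in a :class:`ParameterSet`.
Each uncertain parameter carries a base value, a (low, high) range used for
one-way sensitivity analysis, and a distribution family used for probabilistic
sensitivity analysis.  The default configuration ships with the package as a
YAML file and represents the base case of the analysis: a 56-year-old Taiwanese
woman with early breast cancer receiving six 21-day cycles of a high-FN-risk
regimen, evaluated from the National Health Insurance payer perspective in
2022 New Taiwan Dollars (NTD).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ParameterError",
    "DrugSpec",
    "ParameterSet",
    "Strategy",
    "load_parameters",
    "default_parameters",
    "convert_or_to_rr",
    "base_strategies",
    "scenario2_strategies",
    "strategy_by_id",
]


class ParameterError(ValueError):
    """Raised when a configuration value is missing or out of range."""


def convert_or_to_rr(or_value: float, baseline_p: float) -> float:
    """Convert an odds ratio to a risk ratio at a given baseline risk.

    Uses RR = OR / (1 - p + p * OR), exact for a 2x2 table with
    unexposed risk ``baseline_p``.

    Parameters
    ----------
    or_value : odds ratio, must be positive.
    baseline_p : risk in the unexposed group, in [0, 1).

    Returns
    -------
    float
        The implied risk ratio.  Equals ``or_value`` when the outcome is
        rare (``baseline_p`` → 0) and 1.0 for a null odds ratio.
    """
    if or_value <= 0:
        raise ParameterError(f"odds ratio must be positive, got {or_value}")
    if not 0 <= baseline_p < 1:
        raise ParameterError(
            f"baseline risk must be in [0, 1), got {baseline_p}"
        )
    return or_value / (1.0 - baseline_p + baseline_p * or_value)


@dataclass(frozen=True)
class DrugSpec:
    """One G-CSF product: price, schedule and FN-prevention effectiveness.

    Short-acting drugs (filgrastim, lenograstim) are injected daily for
    ``injections_per_cycle`` days per chemotherapy cycle; the long-acting
    pegfilgrastim is a single injection per cycle.  Effectiveness is a
    relative risk of FN versus no prophylaxis, tiered by chemotherapy cycle
    number (cycles 1–2 vs cycles 3+).  A biosimilar sets ``reference`` to
    its originator and inherits the originator's relative risks, differing
    only in unit price.
    """

    name: str
    price: float
    injections_per_cycle: int
    rr_cycles_1_2: float | None = None
    rr_cycles_3plus: float | None = None
    reference: str | None = None


# scalar ParameterSet fields that can be addressed by name in OWSA/PSA
_SCALAR_FIELDS = (
    "p_fn_cycle1",
    "rr_cycle2plus",
    "rr_history",
    "p_fn_death",
    "p_rdi_low_base",
    "or_rdi_low",
    "hr_rdi_low",
    "u_chemo",
    "u_fn_decrement",
    "u_surv_1_5",
    "u_surv_5plus",
    "cost_fn_event",
    "los_fn",
    "annual_bc_mortality",
    "discount_rate",
)

_PROBABILITY_FIELDS = {
    "p_fn_cycle1",
    "p_fn_death",
    "p_rdi_low_base",
    "u_chemo",
    "u_fn_decrement",
    "u_surv_1_5",
    "u_surv_5plus",
    "annual_bc_mortality",
}
_POSITIVE_FIELDS = {
    "rr_cycle2plus",
    "rr_history",
    "or_rdi_low",
    "hr_rdi_low",
    "cost_fn_event",
    "los_fn",
}


@dataclass(frozen=True)
class ParameterSet:
    """All model inputs with uncertainty metadata.

    ``ranges`` maps a parameter name to its (low, high) one-way sensitivity
    range and ``dist_family`` maps it to a PSA distribution family in
    {"beta", "gamma", "lognormal", "fixed"}.  Drug-level parameters are
    addressed as ``rr_<drug>_c12`` / ``rr_<drug>_c3plus`` (single name
    ``rr_pegfilgrastim`` for the long-acting drug, which has one RR for all
    cycles) and ``price_<drug>``.
    """

    # FN risk structure
    p_fn_cycle1: float = 0.364
    rr_cycle2plus: float = 0.46
    rr_history: float = 2.4
    p_fn_death: float = 0.036
    # relative dose intensity
    p_rdi_low_base: float = 0.247
    or_rdi_low: float = 1.58
    hr_rdi_low: float = 1.73
    # utilities (per year)
    u_chemo: float = 0.78
    u_fn_decrement: float = 0.36
    u_surv_1_5: float = 0.84
    u_surv_5plus: float = 0.91
    # costs (NTD) and resource use
    cost_fn_event: float = 8287.0
    los_fn: float = 10.53
    gcsf_days: int = 4
    # mortality and discounting
    annual_bc_mortality: float = 0.0202
    bc_mortality_years: int = 10
    discount_rate: float = 0.03
    wtp: float = 976_914.0
    # structure
    start_age: int = 56
    n_cycles: int = 6
    cycle_days: int = 21
    age_cap: int = 110
    # drugs and uncertainty metadata
    drugs: Mapping[str, DrugSpec] = field(default_factory=dict)
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    dist_family: Mapping[str, str] = field(default_factory=dict)

    # -- name-based access -------------------------------------------------

    def value_of(self, name: str) -> float:
        """Return the current value of a parameter addressed by name."""
        if name in _SCALAR_FIELDS:
            return getattr(self, name)
        if name.startswith("price_"):
            return self._drug_of(name[len("price_"):]).price
        if name.startswith("rr_"):
            drug, tier = self._split_rr_name(name)
            spec = self._drug_of(drug)
            return spec.rr_cycles_1_2 if tier == "c12" else spec.rr_cycles_3plus
        raise ParameterError(f"unknown parameter {name!r}")

    def with_value(self, name: str, value: float) -> "ParameterSet":
        """Return a copy of this set with one named parameter replaced."""
        if name in _SCALAR_FIELDS:
            self._check_scalar(name, value)
            return dataclasses.replace(self, **{name: value})
        if name.startswith("price_"):
            drug = name[len("price_"):]
            if value <= 0:
                raise ParameterError(f"{name} must be positive, got {value}")
            spec = dataclasses.replace(self._drug_of(drug), price=float(value))
            return self._replace_drug(drug, spec)
        if name.startswith("rr_"):
            drug, tier = self._split_rr_name(name)
            if value <= 0:
                raise ParameterError(f"{name} must be positive, got {value}")
            spec = self._drug_of(drug)
            if tier == "both":
                spec = dataclasses.replace(
                    spec, rr_cycles_1_2=float(value), rr_cycles_3plus=float(value)
                )
            elif tier == "c12":
                spec = dataclasses.replace(spec, rr_cycles_1_2=float(value))
            else:
                spec = dataclasses.replace(spec, rr_cycles_3plus=float(value))
            return self._replace_drug(drug, spec)
        raise ParameterError(f"unknown parameter {name!r}")

    def drug_rr_tiers(self, drug: str) -> tuple[float, float]:
        """Resolve a drug's (cycles 1–2, cycles 3+) relative risks.

        Biosimilars delegate to their reference product.
        """
        spec = self._drug_of(drug)
        if spec.reference is not None:
            return self.drug_rr_tiers(spec.reference)
        if spec.rr_cycles_1_2 is None or spec.rr_cycles_3plus is None:
            raise ParameterError(f"drug {drug!r} has no effectiveness data")
        return spec.rr_cycles_1_2, spec.rr_cycles_3plus

    def _drug_of(self, drug: str) -> DrugSpec:
        try:
            return self.drugs[drug]
        except KeyError:
            raise ParameterError(f"unknown drug {drug!r}") from None

    def _replace_drug(self, drug: str, spec: DrugSpec) -> "ParameterSet":
        drugs = dict(self.drugs)
        drugs[drug] = spec
        return dataclasses.replace(self, drugs=drugs)

    def _split_rr_name(self, name: str) -> tuple[str, str]:
        body = name[len("rr_"):]
        if body.endswith("_c12"):
            return body[:-4], "c12"
        if body.endswith("_c3plus"):
            return body[:-7], "c3plus"
        if body in self.drugs:
            # single-RR drug (pegfilgrastim): one name sets both tiers
            return body, "both"
        raise ParameterError(f"unknown parameter {name!r}")

    @staticmethod
    def _check_scalar(name: str, value: float) -> None:
        if name in _PROBABILITY_FIELDS and not 0.0 <= value <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1], got {value}")
        if name in _POSITIVE_FIELDS and value <= 0:
            raise ParameterError(f"{name} must be positive, got {value}")
        if name == "discount_rate" and value < 0:
            raise ParameterError(f"{name} must be non-negative, got {value}")

    # -- validation and (de)serialisation ----------------------------------

    def validate(self) -> "ParameterSet":
        for name in _SCALAR_FIELDS:
            self._check_scalar(name, getattr(self, name))
        if self.gcsf_days <= 0 or self.cycle_days <= 0 or self.n_cycles <= 0:
            raise ParameterError("structural counts must be positive")
        if self.age_cap <= self.start_age:
            raise ParameterError("age_cap must exceed start_age")
        for dname, spec in self.drugs.items():
            if spec.price <= 0:
                raise ParameterError(f"price of {dname} must be positive")
            if spec.reference is not None and spec.reference not in self.drugs:
                raise ParameterError(
                    f"biosimilar {dname} references unknown drug {spec.reference!r}"
                )
        for name, (low, high) in self.ranges.items():
            base = self.value_of(name)
            if not low <= base <= high:
                raise ParameterError(
                    f"range of {name} must bracket the base value: "
                    f"{low} <= {base} <= {high} fails"
                )
        for name, family in self.dist_family.items():
            if family not in {"beta", "gamma", "lognormal", "fixed"}:
                raise ParameterError(
                    f"unknown distribution family {family!r} for {name}"
                )
            self.value_of(name)  # name must resolve
        return self

    def to_dict(self) -> dict:
        """Nested plain-dict form, round-trippable through YAML."""
        out: dict = {name: getattr(self, name) for name in _SCALAR_FIELDS}
        out.update(
            gcsf_days=self.gcsf_days,
            bc_mortality_years=self.bc_mortality_years,
            wtp=self.wtp,
            start_age=self.start_age,
            n_cycles=self.n_cycles,
            cycle_days=self.cycle_days,
            age_cap=self.age_cap,
        )
        out["drugs"] = {
            name: {
                k: v
                for k, v in dataclasses.asdict(spec).items()
                if k != "name" and v is not None
            }
            for name, spec in sorted(self.drugs.items())
        }
        out["ranges"] = {k: list(v) for k, v in sorted(self.ranges.items())}
        out["dist_family"] = dict(sorted(self.dist_family.items()))
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "ParameterSet":
        data = dict(data)
        drugs_raw = data.pop("drugs", {})
        drugs = {
            name: DrugSpec(name=name, **spec) for name, spec in drugs_raw.items()
        }
        ranges = {
            k: (float(v[0]), float(v[1]))
            for k, v in data.pop("ranges", {}).items()
        }
        dist_family = dict(data.pop("dist_family", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown configuration keys: {sorted(unknown)}")
        ps = cls(drugs=drugs, ranges=ranges, dist_family=dist_family, **data)
        return ps.validate()


def load_parameters(source: str | Path | Mapping) -> ParameterSet:
    """Load and validate a :class:`ParameterSet` from YAML or a mapping.

    ``source`` may be a path to a YAML file, a YAML string, or an
    already-parsed mapping.  Raises :class:`ParameterError` naming the
    offending field on any validation failure.
    """
    if isinstance(source, Mapping):
        return ParameterSet.from_dict(source)
    text = str(source)
    if "\n" not in text:
        try:
            if Path(text).exists():
                text = Path(text).read_text()
        except OSError:
            pass
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ParameterError("configuration must be a mapping")
    return ParameterSet.from_dict(data)


def default_parameters() -> ParameterSet:
    """The packaged base-case configuration."""
    ref = resources.files("gcsf_cea.data").joinpath("basecase.yaml")
    return load_parameters(yaml.safe_load(ref.read_text()))


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# strategies


@dataclass(frozen=True)
class Strategy:
    """A prophylaxis policy: when G-CSF is given, and which product.

    ``mode`` is one of ``"none"`` (no prophylaxis), ``"primary"`` (G-CSF in
    every cycle from cycle 1) or ``"secondary"`` (G-CSF in every cycle after
    a first FN event).  ``drug`` is absent exactly when ``mode == "none"``.
    """

    mode: str
    drug: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"none", "primary", "secondary"}:
            raise ParameterError(f"unknown prophylaxis mode {self.mode!r}")
        if (self.mode == "none") != (self.drug is None):
            raise ParameterError("mode 'none' if and only if drug is absent")
        if self.label is None:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.mode == "none":
            return "No G-CSF prophylaxis"
        prefix = "PP" if self.mode == "primary" else "SP"
        pretty = self.drug.replace("_biosimilar", " biosimilar")
        return f"{prefix} with {pretty}"

    @property
    def id(self) -> str:
        if self.mode == "none":
            return "none"
        return f"{'pp' if self.mode == 'primary' else 'sp'}_{self.drug}"


_REFERENCE_DRUGS = ("filgrastim", "lenograstim", "pegfilgrastim")
_BIOSIMILARS = ("filgrastim_biosimilar", "pegfilgrastim_biosimilar")


def base_strategies() -> list[Strategy]:
    """The seven base-case strategies: none + SP/PP for each reference drug."""
    out = [Strategy("none")]
    for drug in _REFERENCE_DRUGS:
        out.append(Strategy("secondary", drug))
    for drug in _REFERENCE_DRUGS:
        out.append(Strategy("primary", drug))
    return out


def scenario2_strategies() -> list[Strategy]:
    """Base strategies plus SP/PP with the filgrastim and pegfilgrastim biosimilars."""
    out = base_strategies()
    for drug in _BIOSIMILARS:
        out.append(Strategy("secondary", drug))
    for drug in _BIOSIMILARS:
        out.append(Strategy("primary", drug))
    return out


def strategy_by_id(sid: str) -> Strategy:
    """Resolve a short strategy id like ``pp_pegfilgrastim`` or ``none``."""
    for s in scenario2_strategies():
        if s.id == sid:
            return s
    raise ParameterError(f"unknown strategy id {sid!r}")
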