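"""Prediction-task registry: endpoints, transforms, and risk thresholds.

Each assay endpoint is one regression task of a multi-task model. A task
carries the raw assay quantity and its units, the transform used to put
values on model scale (log10, pIC50, or identity), an optional pair of
low/high risk rules expressed on the raw scale, and the model group
(permeability, clearance, binding/lipophilicity, CYP inhibition) whose
multi-task network it belongs to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml

MODEL_GROUPS = (
    "permeability",
    "clearance",
    "binding_lipophilicity",
    "cyp_inhibition",
)

RAW_QUANTITIES = (
    "P_app",        # 10^-6 cm/s
    "CL_int",       # uL min^-1 mg^-1
    "F_u",          # fraction unbound
    "LogP",
    "LogD",
    "k_obs",        # min^-1
    "IC_50",        # uM
    "efflux_ratio",
)

TRANSFORMS = ("log10", "neg_log10_molar", "identity")

_OPS = {
    "<": lambda v, t: v < t,
    "<=": lambda v, t: v <= t,
    ">": lambda v, t: v > t,
    ">=": lambda v, t: v >= t,
}


class RegistryError(ValueError):
    """Invalid task definition or registry."""


@dataclass(frozen=True)
class RiskRule:
    """One comparison against a threshold on the raw assay scale."""

    op: str
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise RegistryError(f"unknown comparison operator {self.op!r}")

    def satisfied(self, raw_value: float) -> bool:
        return _OPS[self.op](raw_value, self.threshold)

    def interval(self) -> tuple[float, float, bool, bool]:
        """Satisfying set as (lo, hi, lo_closed, hi_closed)."""
        if self.op == "<":
            return (-math.inf, self.threshold, False, False)
        if self.op == "<=":
            return (-math.inf, self.threshold, False, True)
        if self.op == ">":
            return (self.threshold, math.inf, False, False)
        return (self.threshold, math.inf, True, False)


def _rules_overlap(a: RiskRule, b: RiskRule) -> bool:
    lo_a, hi_a, loc_a, hic_a = a.interval()
    lo_b, hi_b, loc_b, hic_b = b.interval()
    lo = max(lo_a, lo_b)
    hi = min(hi_a, hi_b)
    if lo < hi:
        return True
    if lo == hi:
        # Shared single point: overlapping only if closed on both sides.
        closed_at_lo = (loc_a if lo == lo_a else True) and (loc_b if lo == lo_b else True)
        closed_at_hi = (hic_a if hi == hi_a else True) and (hic_b if hi == hi_b else True)
        return closed_at_lo and closed_at_hi
    return False


@dataclass(frozen=True)
class TaskSpec:
    """One prediction task of a multi-task model."""

    task_id: str
    model_group: str
    raw_quantity: str
    transform: str
    low_risk_rule: Optional[RiskRule] = None
    high_risk_rule: Optional[RiskRule] = None
    evaluated: bool = False
    # Optional per-task dynamic range on the raw scale; values outside are
    # excluded at ingestion (assay dynamic ranges are lab-specific).
    dynamic_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.model_group not in MODEL_GROUPS:
            raise RegistryError(f"{self.task_id}: unknown model group {self.model_group!r}")
        if self.raw_quantity not in RAW_QUANTITIES:
            raise RegistryError(f"{self.task_id}: unknown raw quantity {self.raw_quantity!r}")
        if self.transform not in TRANSFORMS:
            raise RegistryError(f"{self.task_id}: unknown transform {self.transform!r}")
        if (self.low_risk_rule is None) != (self.high_risk_rule is None):
            raise RegistryError(f"{self.task_id}: risk rules must be given in pairs")
        if self.low_risk_rule is not None and self.high_risk_rule is not None:
            if _rules_overlap(self.low_risk_rule, self.high_risk_rule):
                raise RegistryError(
                    f"{self.task_id}: low- and high-risk rules overlap"
                )

    @property
    def has_risk_rules(self) -> bool:
        return self.low_risk_rule is not None

    def to_model_scale(self, raw: float) -> float:
        """Transform a raw assay value to the model (training) scale."""
        if self.transform == "identity":
            return float(raw)
        if self.transform == "log10":
            if raw <= 0:
                raise ValueError(
                    f"{self.task_id}: raw value {raw} outside log10 domain"
                )
            return math.log10(raw)
        # pIC50 with the molar convention: IC50 given in uM, 1 uM -> 6.
        if raw <= 0:
            raise ValueError(f"{self.task_id}: IC50 {raw} uM outside pIC50 domain")
        return 6.0 - math.log10(raw)

    def from_model_scale(self, value: float) -> float:
        """Invert :meth:`to_model_scale`."""
        if self.transform == "identity":
            return float(value)
        if self.transform == "log10":
            return 10.0 ** value
        return 10.0 ** (6.0 - value)


def fraction_unbound_from_percent_bound(percent_bound: float) -> float:
    """Convert a plasma-protein-binding readout in %bound to F_u."""
    if not 0.0 <= percent_bound <= 100.0:
        raise ValueError(f"percent bound {percent_bound} outside [0, 100]")
    return 1.0 - percent_bound / 100.0


def _spec_from_dict(entry: dict) -> TaskSpec:
    def rule(key: str) -> Optional[RiskRule]:
        r = entry.get(key)
        return None if r is None else RiskRule(op=r["op"], threshold=float(r["threshold"]))

    rng = entry.get("dynamic_range")
    return TaskSpec(
        task_id=entry["task_id"],
        model_group=entry["model_group"],
        raw_quantity=entry["raw_quantity"],
        transform=entry["transform"],
        low_risk_rule=rule("low_risk"),
        high_risk_rule=rule("high_risk"),
        evaluated=bool(entry.get("evaluated", False)),
        dynamic_range=None if rng is None else (float(rng[0]), float(rng[1])),
    )


def load_registry(path: str | Path | None = None) -> list[TaskSpec]:
    """Load a task registry from YAML (default: the 25-task registry)."""
    if path is None:
        text = resources.files("tpd_qspr.data").joinpath("tasks.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    specs = [_spec_from_dict(e) for e in raw["tasks"]]
    ids = [s.task_id for s in specs]
    if len(set(ids)) != len(ids):
        raise RegistryError("duplicate task_id in registry")
    return specs


def default_registry() -> list[TaskSpec]:
    """The packaged 25-task registry (4 model groups, 5/6/10/4 tasks)."""
    return load_registry()


def registry_by_group(registry: Sequence[TaskSpec]) -> dict[str, list[TaskSpec]]:
    out: dict[str, list[TaskSpec]] = {g: [] for g in MODEL_GROUPS}
    for spec in registry:
        out[spec.model_group].append(spec)
    return out


def registry_hash(registry: Sequence[TaskSpec]) -> str:
    """Stable fingerprint of a registry, stored alongside model checkpoints."""
    import hashlib

    h = hashlib.sha256()
    for s in registry:
        lo = "-" if s.low_risk_rule is None else f"{s.low_risk_rule.op}{s.low_risk_rule.threshold}"
        hi = "-" if s.high_risk_rule is None else f"{s.high_risk_rule.op}{s.high_risk_rule.threshold}"
        h.update(f"{s.task_id}|{s.model_group}|{s.raw_quantity}|{s.transform}|{lo}|{hi}\n".encode())
    return h.hexdigest()[:16]
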