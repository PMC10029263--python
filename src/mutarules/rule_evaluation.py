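"""Rule validity scoring and stratified transformation-validity statistics.

A rule's validity ``S_validity = N_neg / N_total`` is the fraction of its
in-domain generated products the consensus model predicts Ames negative;
rules above 0.5 are called high-quality.  Stratum-level transformation
validity ``S_t.v. = N_neg / N_gen`` aggregates products by environment
radius, rule-frequency bucket, or cut category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import applicability_domain as ad
from .chem_io import NEGATIVE
from .mmpa_engine import TransformationRule, frequency_bucket
from .rule_application import GeneratedCompound

HIGH_QUALITY_THRESHOLD = 0.5

# frequency bucketings: coarse three-way split for the frequency-effect
# analysis, and the four-way split matching the rule-summary table
FREQUENCY_BUCKETS = {
    "coarse": lambda f: "1" if f == 1 else ("2-3" if f <= 3 else ">3"),
    "summary": frequency_bucket,
}


@dataclass(frozen=True)
class RuleEvaluation:
    """Per-rule validity over its in-domain products.

    ``s_validity`` is None (rule unevaluable) when the rule produced no
    in-domain products.
    """

    rule_id: str
    n_total: int
    n_neg: int

    @property
    def s_validity(self) -> float | None:
        return self.n_neg / self.n_total if self.n_total else None

    @property
    def evaluable(self) -> bool:
        return self.n_total > 0

    @property
    def high_quality(self) -> bool:
        s = self.s_validity
        return s is not None and s > HIGH_QUALITY_THRESHOLD


@dataclass(frozen=True)
class StratumStats:
    """Aggregated transformation validity for one stratum."""

    key: str
    n_gen: int
    n_neg: int
    n_rules: int

    @property
    def s_tv(self) -> float:
        return self.n_neg / self.n_gen if self.n_gen else float("nan")


def score_rules(
    generated: Iterable[GeneratedCompound],
    rule_ids: Sequence[str] | None = None,
) -> list[RuleEvaluation]:
    """S_validity per rule, counting only in-domain products.

    ``rule_ids`` optionally lists every rule that was applied, so rules with
    zero in-domain products still appear (flagged unevaluable).
    """
    totals: dict[str, int] = {}
    negs: dict[str, int] = {}
    for rid in rule_ids or ():
        totals.setdefault(rid, 0)
        negs.setdefault(rid, 0)
    for g in generated:
        if g.domain_status != ad.IN_DOMAIN:
            continue
        totals[g.rule_id] = totals.get(g.rule_id, 0) + 1
        if g.predicted_label == NEGATIVE:
            negs[g.rule_id] = negs.get(g.rule_id, 0) + 1
    return [
        RuleEvaluation(rid, totals[rid], negs.get(rid, 0)) for rid in sorted(totals)
    ]


def high_quality_proportion(evaluations: Sequence[RuleEvaluation]) -> float:
    """Share of evaluable rules with S_validity above the threshold."""
    evaluable = [e for e in evaluations if e.evaluable]
    if not evaluable:
        return float("nan")
    return sum(e.high_quality for e in evaluable) / len(evaluable)


def filter_rules(
    evaluations: Sequence[RuleEvaluation], min_usage: int = 10
) -> tuple[list[RuleEvaluation], dict]:
    """Keep rules used at least ``min_usage`` times (by ID product count).

    Returns the filtered evaluations plus the high-quality proportions
    before and after filtering (unevaluable rules excluded from both
    denominators).
    """
    kept = [e for e in evaluations if e.n_total >= min_usage]
    report = {
        "min_usage": min_usage,
        "n_rules_before": sum(e.evaluable for e in evaluations),
        "n_rules_after": len(kept),
        "high_quality_before": high_quality_proportion(evaluations),
        "high_quality_after": high_quality_proportion(kept),
    }
    return kept, report


def stratify(
    generated: Iterable[GeneratedCompound],
    rules: Mapping[str, TransformationRule] | Sequence[TransformationRule],
    by: str,
    frequency_buckets: str = "coarse",
) -> list[StratumStats]:
    """Transformation validity per stratum of in-domain products.

    ``by`` is one of ``radius`` (the minimum environment radius each product
    was generated at), ``frequency`` (the generating rule's frequency,
    bucketed) or ``category`` (single/double/triple cut).  Empty strata are
    omitted.
    """
    if not isinstance(rules, Mapping):
        rules = {r.rule_id: r for r in rules}
    if by not in {"radius", "frequency", "category"}:
        raise ValueError(f"unknown stratification key {by!r}")
    bucket = FREQUENCY_BUCKETS[frequency_buckets]

    n_gen: dict[str, int] = {}
    n_neg: dict[str, int] = {}
    used_rules: dict[str, set[str]] = {}
    for g in generated:
        if g.domain_status != ad.IN_DOMAIN:
            continue
        rule = rules[g.rule_id]
        if by == "radius":
            key = str(g.min_radius)
        elif by == "frequency":
            key = bucket(rule.frequency)
        else:
            key = rule.category
        n_gen[key] = n_gen.get(key, 0) + 1
        if g.predicted_label == NEGATIVE:
            n_neg[key] = n_neg.get(key, 0) + 1
        used_rules.setdefault(key, set()).add(g.rule_id)
    return [
        StratumStats(key, n_gen[key], n_neg.get(key, 0), len(used_rules[key]))
        for key in sorted(n_gen)
    ]


def evaluations_to_frame(evaluations: Sequence[RuleEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rule_id": e.rule_id,
                "N_total": e.n_total,
                "N_neg": e.n_neg,
                "S_validity": e.s_validity,
                "high_quality": e.high_quality,
                "evaluable": e.evaluable,
            }
            for e in evaluations
        ],
        columns=["rule_id", "N_total", "N_neg", "S_validity", "high_quality", "evaluable"],
    )


def strata_to_frame(strata: Sequence[StratumStats], key_name: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                key_name: s.key,
                "N_gen": s.n_gen,
                "N_neg": s.n_neg,
                "S_tv": s.s_tv,
                "N_rules": s.n_rules,
            }
            for s in strata
        ],
        columns=[key_name, "N_gen", "N_neg", "S_tv", "N_rules"],
    )
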