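"""Rule engine: conjunction-of-thresholds searches over the score table.

The five stock searches target distinct temporal archetypes of a
responder-specific gene:

1. similar group baselines that diverge strongly later
   (``sim < 0.6 & diff26 > 5``);
2. consistently up in responders while down in non-responders
   (``tscoreR > 8 & tscoreN < 0 & sim < 0.1 & SignifR > 5``);
3. strongly up in responders, essentially flat in non-responders
   (``tscoreR > 6 & tscoreN = -1 & sim < 0.1 & absFCR > 10.5 & absFCN < 2.5``);
4. significant up-regulation in exactly 6 of 7 responders and no significant
   change in any non-responder
   (``NumSigPos = 6 & NumSigNeg = -1 & SignifN = 0``);
5. as (4) but in exactly 5 of 7 responders.

Rule 5's count comparator defaults to strict equality, which keeps rules 4
and 5 disjoint; pass ``rule5_ge=True`` for the ">= 5" reading.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SCORE_FIELDS, SelectionRule

__all__ = ["SelectionResult", "apply_rule", "default_rules", "select_genes",
           "EQUALITY_TOLERANCE"]

#: tolerance for '=' comparisons on real-valued scores (integer scores compare
#: exactly because their float representation is exact)
EQUALITY_TOLERANCE = 1e-9

_OPS = {
    "<": operator.lt,
    ">": operator.gt,
    ">=": operator.ge,
    "<=": operator.le,
}


@dataclass
class SelectionResult:
    """Per-rule gene lists, their union, and per-gene matched-rule names."""

    per_rule: dict[str, list[str]]
    union: list[str]
    annotations: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, ";".join(rules)) for g, rules in self.annotations.items()]
        return pd.DataFrame(rows, columns=["gene", "matched_rules"])


def apply_rule(scores: pd.DataFrame, rule: SelectionRule) -> list[str]:
    """Genes satisfying every predicate of the rule, sorted by gene id.

    Genes with a missing (NaN) value in any referenced score are excluded.
    """
    keep = np.ones(len(scores), dtype=bool)
    for fld, op, threshold in rule.predicates:
        if fld not in scores.columns:
            raise KeyError(
                f"rule {rule.name!r} references unknown score field {fld!r}; "
                f"known fields: {list(SCORE_FIELDS)}"
            )
        col = scores[fld].to_numpy(dtype=float)
        if op == "=":
            ok = np.abs(col - threshold) <= EQUALITY_TOLERANCE
        else:
            ok = _OPS[op](col, threshold)
        ok &= ~np.isnan(col)
        keep &= ok
    return sorted(scores.index[keep])


def default_rules(rule5_ge: bool = False) -> list[SelectionRule]:
    """The five stock score-combination searches (see module docstring)."""
    r5_op = ">=" if rule5_ge else "="
    return [
        SelectionRule("similar_start_diverging", (
            ("sim", "<", 0.6), ("diff26", ">", 5.0))),
        SelectionRule("up_in_R_down_in_N", (
            ("tscoreR", ">", 8.0), ("tscoreN", "<", 0.0),
            ("sim", "<", 0.1), ("SignifR", ">", 5.0))),
        SelectionRule("up_in_R_flat_in_N", (
            ("tscoreR", ">", 6.0), ("tscoreN", "=", -1.0),
            ("sim", "<", 0.1), ("absFCR", ">", 10.5), ("absFCN", "<", 2.5))),
        SelectionRule("up_in_6_of_7_responders", (
            ("NumSigPos", "=", 6.0), ("NumSigNeg", "=", -1.0),
            ("SignifN", "=", 0.0))),
        SelectionRule("up_in_5_of_7_responders", (
            ("NumSigPos", r5_op, 5.0), ("NumSigNeg", "=", -1.0),
            ("SignifN", "=", 0.0))),
    ]


def select_genes(scores: pd.DataFrame,
                 rules: list[SelectionRule] | None = None) -> SelectionResult:
    """Apply every rule and collect per-rule lists, union and annotations."""
    if scores.empty:
        raise ValueError("empty score table")
    if rules is None:
        rules = default_rules()
    per_rule = {rule.name: apply_rule(scores, rule) for rule in rules}
    annotations: dict[str, list[str]] = {}
    for name, genes in per_rule.items():
        for g in genes:
            annotations.setdefault(g, []).append(name)
    union = sorted(annotations)
    return SelectionResult(per_rule=per_rule, union=union,
                           annotations=annotations)
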