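"""Rule-based potency classifier and ranker for DB-lipidoids.

Three validated structural criteria define a predicted-potent lipidoid:

1. **18-Carbon Rule** — total tail carbons TC = m + n = 18.
2. **Symmetry** — deviation d = |n/(m-2) - 1| at most ``d_max``
   (default 1.0: admits the near-symmetric d = 0.7 and 0.4 combinations,
   excludes the failed d = 2 one).
3. **Headgroup** — efficacious diamine class (one primary + one
   dimethylamino/diethylamino/pyrrolidinyl tertiary amine, 2-3 carbon
   spacer, no hydrazine).

A continuous ``rank_score`` (lower is better) orders candidates: compliant
lipidoids rank by d alone; each violated criterion adds a penalty large
enough that any violator ranks below every compliant candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .building_blocks import Registry
from .descriptors import DescriptorSet, describe_library
from .enumerator import LibraryDesign, enumerate_library
from .errors import ValidationError

TARGET_TOTAL_CARBONS = 18


@dataclass(frozen=True)
class RuleConfig:
    d_max: float = 1.0
    penalty: float = 100.0

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValidationError("d_max must be positive")


@dataclass(frozen=True)
class RuleVerdict:
    name: str
    c1_total18: bool
    c2_symmetry: bool
    c3_headgroup: bool
    predicted_potent: bool
    rank_score: float
    notes: tuple[str, ...] = ()


def evaluate(descriptors: DescriptorSet, config: RuleConfig = RuleConfig()) -> RuleVerdict:
    """Apply the three structural criteria to one lipidoid's descriptors."""
    tails = descriptors.tails
    notes: list[str] = []
    c1 = tails.total_carbons == TARGET_TOTAL_CARBONS
    if not c1:
        notes.append(f"total carbons {tails.total_carbons} != {TARGET_TOTAL_CARBONS}")
    c2 = tails.deviation <= config.d_max
    if not c2:
        notes.append(f"symmetry deviation {tails.deviation:.2f} > {config.d_max}")
    c3 = descriptors.headgroup.is_efficacious_class
    if not c3:
        notes.append("headgroup outside the efficacious diamine class")
    score = (
        tails.deviation
        + config.penalty * abs(tails.total_carbons - TARGET_TOTAL_CARBONS)
        + config.penalty * (0 if c3 else 1)
    )
    return RuleVerdict(
        name=descriptors.name,
        c1_total18=c1,
        c2_symmetry=c2,
        c3_headgroup=c3,
        predicted_potent=c1 and c2 and c3,
        rank_score=score,
        notes=tuple(notes),
    )


def rank(verdicts: Sequence[RuleVerdict]) -> list[RuleVerdict]:
    """Stable sort ascending by rank_score, ties broken by name."""
    return sorted(verdicts, key=lambda v: (v.rank_score, v.name))


@dataclass
class ScreenSummary:
    n_candidates: int
    n_predicted_potent: int
    hit_rate: int | None  # percent, rounded; None when no candidates

    def as_dict(self) -> dict:
        return {
            "n_candidates": self.n_candidates,
            "n_predicted_potent": self.n_predicted_potent,
            "hit_rate": self.hit_rate,
        }


def screen_library(
    registry: Registry,
    designs: LibraryDesign | Sequence[LibraryDesign],
    config: RuleConfig = RuleConfig(),
):
    """Enumerate, describe and evaluate one or more designs.

    Overlapping designs can reach the same (amine, m, n) product twice;
    duplicates are removed by name before counting, so the hit rate refers
    to unique candidates. Returns ``(verdict_table, summary)``.
    """
    import pandas as pd

    if isinstance(designs, LibraryDesign):
        designs = [designs]
    lipidoids = []
    seen: set[str] = set()
    for design in designs:
        for lip in enumerate_library(registry, design):
            if lip.name not in seen:
                seen.add(lip.name)
                lipidoids.append(lip)

    if not lipidoids:
        empty = pd.DataFrame(
            columns=[
                "name", "m", "n", "total_carbons", "symmetry", "deviation",
                "c1_total18", "c2_symmetry", "c3_headgroup",
                "predicted_potent", "rank_score",
            ]
        )
        return empty, ScreenSummary(0, 0, None)

    desc_df = describe_library(lipidoids, registry)
    verdict_rows = []
    for _, row in desc_df.iterrows():
        c1 = row["total_carbons"] == TARGET_TOTAL_CARBONS
        c2 = row["deviation"] <= config.d_max
        c3 = bool(row["hg_is_efficacious_class"])
        score = (
            row["deviation"]
            + config.penalty * abs(row["total_carbons"] - TARGET_TOTAL_CARBONS)
            + config.penalty * (0 if c3 else 1)
        )
        verdict_rows.append(
            {
                "name": row["name"],
                "m": row["m"],
                "n": row["n"],
                "total_carbons": row["total_carbons"],
                "symmetry": row["symmetry"],
                "deviation": row["deviation"],
                "c1_total18": c1,
                "c2_symmetry": c2,
                "c3_headgroup": c3,
                "predicted_potent": bool(c1 and c2 and c3),
                "rank_score": score,
            }
        )
    table = pd.DataFrame(verdict_rows).sort_values(
        ["rank_score", "name"], kind="stable"
    ).reset_index(drop=True)
    n_potent = int(table["predicted_potent"].sum())
    n_cand = len(table)
    summary = ScreenSummary(
        n_candidates=n_cand,
        n_predicted_potent=n_potent,
        hit_rate=round(100 * n_potent / n_cand),
    )
    return table, summary
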