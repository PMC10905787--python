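"""Lipinski rule-of-five screening of herbal components.

The five drug-likeness rules, with the exact boundaries used here:

* R1 — molecular weight strictly below 500 Da;
* R2 — at most 5 hydrogen-bond donors;
* R3 — fewer than 10 hydrogen-bond acceptors;
* R4 — cLogP between -2 and 5 inclusive;
* R5 — at most 10 rotatable bonds.

Components passing every rule are "active components".  Literature-sourced
high-bioactivity components receive no bypass: everything is screened the
same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .records import ComponentRecord

RULES = ("R1", "R2", "R3", "R4", "R5")

_RULE_PROPERTY = {
    "R1": "mw",
    "R2": "hbd",
    "R3": "hba",
    "R4": "clogp",
    "R5": "rotatable_bonds",
}

_RULE_PREDICATE = {
    "R1": lambda mw: mw < 500,
    "R2": lambda hbd: hbd <= 5,
    "R3": lambda hba: hba < 10,
    "R4": lambda clogp: -2 <= clogp <= 5,
    "R5": lambda rot: rot <= 10,
}


@dataclass(frozen=True)
class ScreenVerdict:
    """Outcome of screening one component.

    In strict mode a component with any unknown property cannot pass; in
    lenient mode unknown properties are ignored and only violated rules
    count against it.
    """

    component_id: str
    passed: bool
    failed_rules: frozenset
    unknown_properties: frozenset


def lipinski_verdict(component: ComponentRecord, strict: bool = True) -> ScreenVerdict:
    """Apply the five rules to a single component and return a verdict."""
    failed = set()
    unknown = component.unknown_properties
    for rule in RULES:
        value = getattr(component, _RULE_PROPERTY[rule])
        if value is None:
            continue
        if not _RULE_PREDICATE[rule](value):
            failed.add(rule)
    passed = not failed and (not strict or not unknown)
    return ScreenVerdict(
        component_id=component.component_id,
        passed=passed,
        failed_rules=frozenset(failed),
        unknown_properties=unknown,
    )


def screen_components(
    components: Iterable[ComponentRecord], strict: bool = True
) -> tuple:
    """Screen a component list; return (active components, verdict list).

    Screening is per-component: no cross-component coupling, so the active
    set of a union of lists is the union of the individual active sets.
    """
    components = list(components)
    verdicts = [lipinski_verdict(c, strict=strict) for c in components]
    active = [c for c, v in zip(components, verdicts) if v.passed]
    return active, verdicts


def herb_tally(
    components: Iterable[ComponentRecord],
    verdicts: Optional[Iterable[ScreenVerdict]] = None,
) -> pd.DataFrame:
    """Per-herb collected/active counts plus a Total row.

    A component carried by several herbs counts once under each herb, as in
    the usual per-herb composition tables; the Total row counts distinct
    components, not the column sum, when multi-herb components exist.
    Here the Total of the per-herb columns is also reported
    (``collected_sum``/``active_sum``) because composition tables are
    conventionally totalled that way.
    """
    components = list(components)
    if verdicts is None:
        _, verdicts = screen_components(components)
    passed_ids = {v.component_id for v in verdicts if v.passed}
    herbs = sorted({h for c in components for h in c.herbs})
    rows = []
    for herb in herbs:
        in_herb = [c for c in components if herb in c.herbs]
        rows.append(
            {
                "herb": herb,
                "collected": len(in_herb),
                "active": sum(1 for c in in_herb if c.component_id in passed_ids),
            }
        )
    df = pd.DataFrame(rows, columns=["herb", "collected", "active"])
    total = pd.DataFrame(
        [{
            "herb": "Total",
            "collected": int(df["collected"].sum()),
            "active": int(df["active"].sum()),
        }]
    )
    return pd.concat([df, total], ignore_index=True)


def write_screen_report(verdicts: Iterable[ScreenVerdict], path) -> None:
    """Write a TSV screening report (one row per component)."""
    rows = [
        (
            v.component_id,
            v.passed,
            ";".join(sorted(v.failed_rules)),
            ";".join(sorted(v.unknown_properties)),
        )
        for v in verdicts
    ]
    pd.DataFrame(
        rows, columns=["component_id", "passed", "failed_rules", "unknown_properties"]
    ).to_csv(path, sep="\t", index=False)
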