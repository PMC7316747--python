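"""Case definitions from multi-system subtype assignments.

Given per-sample subtype labels from several classification systems, this
module builds the six case definitions used throughout the package — one
per single system plus *intersect* (assigned the subtype by every listed
system), *union* (by at least one) and *symmetric difference* (union minus
intersect) — together with Cohen's kappa agreement statistics and
case-count tables. The control set is shared by every definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EstimationError, LookupError_
from .simdata import UNDETERMINED, Cohort

SET_KINDS = ("intersect", "union", "symmetric_difference")


@dataclass
class AssignmentTable:
    """Per-case subtype labels for each classification system.

    ``df`` has one row per case with an ID column and one column per
    system; multi-label entries are semicolon-joined strings. ``controls``
    holds the shared control IDs.
    """

    df: pd.DataFrame
    systems: tuple[str, ...]
    subtypes: tuple[str, ...]
    controls: np.ndarray
    undetermined_label: str = UNDETERMINED

    def __post_init__(self) -> None:
        missing = [s for s in self.systems if s not in self.df.columns]
        if missing:
            raise LookupError_(f"assignment table lacks system column(s): {missing}")
        universe = set(self.subtypes) | {self.undetermined_label}
        for system in self.systems:
            for entry in self.df[system]:
                for lab in str(entry).split(";"):
                    if lab not in universe:
                        raise LookupError_(
                            f"label {lab!r} in system {system} outside the declared universe"
                        )

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "AssignmentTable":
        cases = cohort.samples[cohort.samples["STATUS"] == "case"]
        cols = ["ID", *cohort.config.systems]
        return cls(
            df=cases[cols].reset_index(drop=True),
            systems=tuple(cohort.config.systems),
            subtypes=tuple(cohort.config.subtypes),
            controls=cohort.control_ids,
        )

    def label_set(self, system: str, row_labels: str) -> frozenset:
        return frozenset(str(row_labels).split(";"))

    def assigned(self, system: str, subtype: str) -> np.ndarray:
        """Boolean mask over case rows: subtype in the system's label set."""
        if system not in self.systems:
            raise LookupError_(f"unknown system {system!r}")
        if subtype not in self.subtypes:
            raise LookupError_(f"unknown subtype {subtype!r}")
        col = self.df[system].astype(str)
        return col.str.split(";").map(lambda labs: subtype in labs).to_numpy()


@dataclass
class PhenotypeDefinition:
    """A named case set plus the shared control set."""

    name: str
    kind: str
    subtype: str
    case_ids: np.ndarray
    control_ids: np.ndarray

    def __post_init__(self) -> None:
        if set(self.case_ids) & set(self.control_ids):
            raise LookupError_(f"{self.name}: case and control sets overlap")

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)


def build_definition(
    table: AssignmentTable,
    subtype: str,
    kind: str,
    systems: tuple[str, ...] | None = None,
) -> PhenotypeDefinition:
    """Build one case definition for ``subtype``.

    ``kind`` is a system name (pass-through) or one of
    ``intersect`` / ``union`` / ``symmetric_difference`` over ``systems``
    (default: all systems of the table). 'undetermined' never counts as an
    assignment to a subtype. Cases outside the definition are simply not
    in ``case_ids``; the control set is unchanged.
    """
    if subtype not in table.subtypes:
        raise LookupError_(f"unknown subtype {subtype!r}")
    if systems is None:
        systems = table.systems
    if not systems:
        raise LookupError_("systems list must be non-empty")
    unknown = [s for s in systems if s not in table.systems]
    if unknown:
        raise LookupError_(f"unknown system(s) {unknown}")

    masks = {s: table.assigned(s, subtype) for s in systems}
    if kind in table.systems:
        if kind not in systems:
            raise LookupError_(f"system {kind!r} not in the systems list")
        mask = masks[kind]
    elif kind == "intersect":
        mask = np.logical_and.reduce([masks[s] for s in systems])
    elif kind == "union":
        mask = np.logical_or.reduce([masks[s] for s in systems])
    elif kind == "symmetric_difference":
        mask = np.logical_or.reduce([masks[s] for s in systems]) & ~np.logical_and.reduce(
            [masks[s] for s in systems]
        )
    else:
        raise LookupError_(f"unknown definition kind {kind!r}")

    ids = table.df.loc[mask, "ID"].to_numpy()
    return PhenotypeDefinition(
        name=f"{subtype}-{kind}",
        kind=kind,
        subtype=subtype,
        case_ids=ids,
        control_ids=np.asarray(table.controls),
    )


@dataclass
class KappaResult:
    kappa: float
    se: float
    p_o: float
    p_e: float
    n: int


def cohens_kappa(labels_a, labels_b) -> KappaResult:
    """Cohen's kappa over the full multi-category table.

    kappa = (p_o - p_e) / (1 - p_e); SE by the large-sample formula
    sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)).
    """
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if a.shape != b.shape:
        raise EstimationError("label vectors must have equal length")
    n = len(a)
    if n == 0:
        raise EstimationError("empty label vectors")
    cats = sorted(set(a) | set(b), key=str)
    idx = {c: i for i, c in enumerate(cats)}
    tab = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        tab[idx[x], idx[y]] += 1
    tab /= n
    p_o = float(np.trace(tab))
    p_e = float(tab.sum(axis=1) @ tab.sum(axis=0))
    if p_e >= 1.0 - 1e-12:
        raise EstimationError("kappa undefined: chance agreement p_e = 1 (single-category data)")
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = float(np.sqrt(max(p_o * (1.0 - p_o), 0.0) / n) / (1.0 - p_e))
    return KappaResult(kappa=float(kappa), se=se, p_o=p_o, p_e=p_e, n=n)


def case_count_table(
    table: AssignmentTable,
    systems: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Case counts per definition (rows) and subtype (columns).

    Single-system rows additionally count 'undetermined' cases (a case
    whose label set contains no subtype); for the set-algebra rows that
    cell is not defined and reported as NA. For single-system rows Total
    is the row sum (a multi-label case contributes to every subtype column
    it is assigned); for the set-algebra rows Total is the number of
    distinct cases in any subtype's definition of that kind.
    """
    if systems is None:
        systems = table.systems
    rows = []
    kinds = list(systems) + list(SET_KINDS)
    for kind in kinds:
        counts = {}
        case_sets = []
        for st in table.subtypes:
            d = build_definition(table, st, kind, systems)
            counts[st] = int(d.n_cases)
            case_sets.append(set(d.case_ids))
        if kind in table.systems:
            is_undet = ~np.logical_or.reduce(
                [table.assigned(kind, st) for st in table.subtypes]
            )
            counts[UNDETERMINED] = int(is_undet.sum())
            counts["Total"] = int(sum(counts[st] for st in table.subtypes) + counts[UNDETERMINED])
        else:
            counts[UNDETERMINED] = pd.NA
            counts["Total"] = len(set().union(*case_sets))
        rows.append(pd.Series(counts, name=kind))
    return pd.DataFrame(rows)
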