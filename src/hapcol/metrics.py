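"""Inter-island colonization metrics.

Four quantities summarise how much inter-island movement a species'
haplotype distribution reveals:

1. chorological minimum — islands occupied minus one: the fewest
   colonization events consistent with presence data alone;
2. maximum potential events — n_haplotypes x (archipelago islands - 1):
   every haplotype could in principle have reached every island, under the
   assumption that each haplotype originated by mutation on a single
   island and then had the whole archipelago available for dispersal;
3. inferred events — read off the actual haplotype x island distribution,
   under one of three sharing rules (see :func:`inferred_events`);
4. colonization success — inferred / maximum potential, in [0, 1].

All three sharing rules are always co-reported, because the literal
"haplotypes on two or more islands" count and the per-haplotype
event-granularity count answer slightly different questions and published
compilations are not explicit about which they used.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

import pandas as pd

from .errors import InputError, UndefinedRatioError
from .haplotypes import HaplotypeTable

INFERRED_RULES = ("shared_count", "per_haplotype_spanning",
                  "spanning_plus_components")
#: Headline rule: one event per island beyond each haplotype's single
#: island of origin — sharing expressed at event granularity.
DEFAULT_RULE = "per_haplotype_spanning"


def chorological_minimum(n_islands_occupied: int) -> int:
    """Fewest colonization events consistent with the species' chorology:
    occupied islands minus one."""
    if n_islands_occupied < 1:
        raise InputError("a species must occupy at least one island")
    return n_islands_occupied - 1


def max_potential(n_haplotypes: int, n_archipelago_islands: int) -> int:
    """Maximum potential colonization events: every haplotype dispersing
    from its island of origin to all remaining archipelago islands."""
    if n_haplotypes < 1:
        raise InputError("need at least one haplotype")
    if n_archipelago_islands < 1:
        raise InputError("need at least one archipelago island")
    return n_haplotypes * (n_archipelago_islands - 1)


def _island_sets(table_or_sets) -> dict:
    if isinstance(table_or_sets, HaplotypeTable):
        return table_or_sets.island_sets()
    if isinstance(table_or_sets, dict):
        return {k: frozenset(v) for k, v in table_or_sets.items()}
    return {i: frozenset(s) for i, s in enumerate(table_or_sets)}


def inferred_events(table, rule: str = DEFAULT_RULE) -> int:
    """Colonization events inferred from the haplotype distribution.

    ``shared_count``
        number of haplotypes present on two or more islands (the literal
        reading of the classical definition);
    ``per_haplotype_spanning``
        sum over haplotypes on k >= 2 islands of (k - 1): each island
        beyond the single island of origin is one event;
    ``spanning_plus_components``
        per_haplotype_spanning + (C - 1), where C is the number of
        connected components of the occupied-island graph whose edges are
        shared haplotypes — the extra term counts the events needed to
        connect island groups that share no haplotype at all.

    ``table`` may be a :class:`HaplotypeTable`, a mapping
    haplotype -> island set, or a plain list of island sets.
    """
    if rule not in INFERRED_RULES:
        raise InputError(f"unknown rule {rule!r}; choose from "
                         f"{INFERRED_RULES}")
    sets = _island_sets(table)
    if not sets:
        raise InputError("empty haplotype table")
    if rule == "shared_count":
        return sum(1 for s in sets.values() if len(s) >= 2)
    spanning = sum(len(s) - 1 for s in sets.values() if len(s) >= 2)
    if rule == "per_haplotype_spanning":
        return spanning
    # spanning_plus_components
    occupied = sorted(set().union(*sets.values()))
    parent = {i: i for i in occupied}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for s in sets.values():
        isl = sorted(s)
        for other in isl[1:]:
            ra, rb = find(isl[0]), find(other)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    n_components = len({find(i) for i in occupied})
    return spanning + (n_components - 1)


def inferred_events_all(table) -> dict:
    """All three sharing rules at once: rule name -> events."""
    return {rule: inferred_events(table, rule) for rule in INFERRED_RULES}


class SuccessRatio(NamedTuple):
    value: float  # full precision
    rounded: float  # half-up to 3 decimals, for display


def round_half_up(x: float, ndigits: int = 3) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{ndigits}"),
                                           rounding=ROUND_HALF_UP))


def colonization_success(inferred: int, max_potential_events: int
                         ) -> SuccessRatio:
    """Inferred / maximum-potential colonization events, in [0, 1]."""
    if max_potential_events == 0:
        raise UndefinedRatioError(
            "colonization success undefined for zero potential events")
    if max_potential_events < 0 or inferred < 0:
        raise InputError("event counts must be non-negative")
    if inferred > max_potential_events:
        raise InputError(
            f"inferred events ({inferred}) exceed the maximum potential "
            f"({max_potential_events})")
    value = inferred / max_potential_events
    return SuccessRatio(value=value, rounded=round_half_up(value, 3))


# ---------------------------------------------------------------------------
# Cross-species report
# ---------------------------------------------------------------------------

@dataclass
class ColonizationRecord:
    """Per-species inputs for the cross-species colonization comparison.

    Either ``sharing`` (per-haplotype island sets, typically from a
    :class:`HaplotypeTable`) or an externally published ``inferred_events``
    count must be supplied.  ``n_archipelago_islands`` is per-record: the
    number of islands the source study considered, not a property of the
    archipelago name.
    """

    species: str
    n_islands_occupied: int
    n_archipelago_islands: int
    n_haplotypes: int
    sharing: list | None = None
    inferred_events: int | None = None
    archipelago: str = ""

    def validate(self) -> None:
        err = lambda msg: InputError(f"record {self.species!r}: {msg}")
        if not (1 <= self.n_islands_occupied <= self.n_archipelago_islands):
            raise err(
                f"islands occupied ({self.n_islands_occupied}) must be in "
                f"[1, {self.n_archipelago_islands}]")
        if self.n_haplotypes < 1:
            raise err("needs at least one haplotype")
        if self.sharing is None and self.inferred_events is None:
            raise err("needs either sharing sets or an inferred event count")
        if self.sharing is not None:
            if len(self.sharing) != self.n_haplotypes:
                raise err(
                    f"{len(self.sharing)} sharing sets for "
                    f"{self.n_haplotypes} haplotypes")
            union = set().union(*[set(s) for s in self.sharing]) \
                if self.sharing else set()
            if len(union) != self.n_islands_occupied:
                raise err(
                    f"union of island sets has size {len(union)}, expected "
                    f"{self.n_islands_occupied}")

    @classmethod
    def from_table(cls, species: str, table: HaplotypeTable,
                   n_archipelago_islands: int, archipelago: str = ""
                   ) -> "ColonizationRecord":
        sets = table.island_sets()
        occupied = set().union(*sets.values())
        return cls(species=species,
                   n_islands_occupied=len(occupied),
                   n_archipelago_islands=n_archipelago_islands,
                   n_haplotypes=table.n_haplotypes,
                   sharing=[sets[h] for h in table.haplotype_ids],
                   archipelago=archipelago)


@dataclass
class MetricsResult:
    """The four metrics for one species, inferred events keyed by rule."""

    species: str
    chorological_min: int
    max_potential: int
    inferred_events: dict  # rule -> events ('external' when supplied)
    success: dict  # rule -> SuccessRatio
    headline_rule: str

    @property
    def headline_success(self) -> SuccessRatio:
        return self.success[self.headline_rule]


def compute_metrics(record: ColonizationRecord,
                    headline_rule: str = DEFAULT_RULE) -> MetricsResult:
    """Compute all four metrics for one species record.

    Records carrying sharing sets get all three rules; records with an
    external published count get the single rule ``external``.
    """
    record.validate()
    mp = max_potential(record.n_haplotypes, record.n_archipelago_islands)
    if record.sharing is not None:
        sets = {i: frozenset(s) for i, s in enumerate(record.sharing)}
        inferred = inferred_events_all(sets)
        rule = headline_rule
    else:
        inferred = {"external": int(record.inferred_events)}
        rule = "external"
    success = {r: colonization_success(v, mp) for r, v in inferred.items()}
    return MetricsResult(species=record.species,
                         chorological_min=chorological_minimum(
                             record.n_islands_occupied),
                         max_potential=mp,
                         inferred_events=inferred,
                         success=success,
                         headline_rule=rule)


REPORT_COLUMNS = [
    "species", "archipelago", "n_islands_occupied", "n_archipelago_islands",
    "n_haplotypes", "chorological_min", "max_potential", "rule",
    "inferred_events", "success", "success_rounded",
    "inferred_shared_count", "inferred_per_haplotype_spanning",
    "inferred_spanning_plus_components",
]


def species_report(records, headline_rule: str = DEFAULT_RULE
                   ) -> pd.DataFrame:
    """Cross-species comparison table, sorted by success descending.

    One row per species with the four metrics and rule provenance; for
    records with sharing sets the per-rule inferred counts are co-reported
    in dedicated columns.  An empty record list yields an empty frame with
    the full header.
    """
    rows = []
    for record in records:
        result = compute_metrics(record, headline_rule=headline_rule)
        row = {
            "species": record.species,
            "archipelago": record.archipelago,
            "n_islands_occupied": record.n_islands_occupied,
            "n_archipelago_islands": record.n_archipelago_islands,
            "n_haplotypes": record.n_haplotypes,
            "chorological_min": result.chorological_min,
            "max_potential": result.max_potential,
            "rule": result.headline_rule,
            "inferred_events": result.inferred_events[result.headline_rule],
            "success": result.headline_success.value,
            "success_rounded": result.headline_success.rounded,
            "inferred_shared_count": result.inferred_events.get(
                "shared_count"),
            "inferred_per_haplotype_spanning": result.inferred_events.get(
                "per_haplotype_spanning"),
            "inferred_spanning_plus_components": result.inferred_events.get(
                "spanning_plus_components"),
        }
        rows.append(row)
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if not frame.empty:
        frame = frame.sort_values(
            ["success", "species"], ascending=[False, True]
        ).reset_index(drop=True)
    return frame


def read_species_table(path) -> list:
    """Read a species-summary TSV into :class:`ColonizationRecord` rows.

    Columns: species, archipelago, n_islands_occupied,
    n_archipelago_islands, n_haplotypes, inferred_events.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"species", "n_islands_occupied", "n_archipelago_islands",
              "n_haplotypes", "inferred_events"}
    missing = needed - set(df.columns)
    if missing:
        raise InputError(f"species table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(ColonizationRecord(
            species=str(row["species"]),
            archipelago=str(row.get("archipelago", "")),
            n_islands_occupied=int(row["n_islands_occupied"]),
            n_archipelago_islands=int(row["n_archipelago_islands"]),
            n_haplotypes=int(row["n_haplotypes"]),
            inferred_events=int(row["inferred_events"]),
        ))
    return records


def report_to_markdown(frame: pd.DataFrame) -> str:
    """Render the cross-species report as a Markdown table."""
    cols = ["species", "archipelago", "n_islands_occupied",
            "n_archipelago_islands", "n_haplotypes", "chorological_min",
            "max_potential", "inferred_events", "success_rounded", "rule"]
    header = "| " + " | ".join(cols) + " |"
    sep = "|" + "|".join(["---"] * len(cols)) + "|"
    lines = [header, sep]
    for _, row in frame.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            if c == "success_rounded" and pd.notna(v):
                cells.append(f"{v:.3f}")
            else:
                cells.append("" if pd.isna(v) else str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
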