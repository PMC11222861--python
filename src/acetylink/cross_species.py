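"""Cross-species DEG intersection (the Venn-diagram logic).

DEG tables from several species are matched on upper-cased gene symbols,
optionally routed through an explicit ortholog map, and intersected with
exact set algebra.  Direction concordance (same sign of log2FC in every
species) is reported but not required for membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class DegSet:
    """One species' differential genes keyed by normalized symbol."""

    species: str
    entries: dict[str, tuple[float, float]] = field(default_factory=dict)
    unmapped: set[str] = field(default_factory=set)

    @property
    def symbols(self) -> set[str]:
        return set(self.entries)


def normalize_symbols(deg_table: pd.DataFrame, species: str,
                      ortholog_map: pd.DataFrame | None = None) -> DegSet:
    """Upper-case symbols, apply an optional source->target ortholog map.

    ``deg_table`` needs columns symbol, log2fc, p.  After mapping,
    duplicate symbols keep the entry with the smaller p-value (warned).
    Symbols absent from the map are kept as-is and flagged in
    ``DegSet.unmapped``.
    """
    required = {"symbol", "log2fc", "p"}
    if not required.issubset(deg_table.columns):
        raise ValueError(f"DEG table needs columns {sorted(required)}")
    mapping: dict[str, str] = {}
    if ortholog_map is not None:
        if not {"source", "target"}.issubset(ortholog_map.columns):
            raise ValueError("ortholog map needs columns source, target")
        mapping = {
            str(s).upper(): str(t).upper()
            for s, t in zip(ortholog_map["source"], ortholog_map["target"])
        }
    out = DegSet(species)
    for _, row in deg_table.iterrows():
        raw = str(row["symbol"]).upper()
        key = mapping.get(raw, raw)
        if ortholog_map is not None and raw not in mapping:
            out.unmapped.add(raw)
        entry = (float(row["log2fc"]), float(row["p"]))
        if key in out.entries:
            log.warning("%s: duplicate symbol %s after mapping; keeping min p",
                        species, key)
            if entry[1] < out.entries[key][1]:
                out.entries[key] = entry
        else:
            out.entries[key] = entry
    return out


def intersect_degs(deg_sets: list[DegSet]
                   ) -> tuple[set[str], dict[str, int], pd.DataFrame]:
    """Full-overlap gene set, all Venn region counts, direction table.

    Venn regions are keyed by the sorted "&"-joined species names of the
    exact membership pattern; counts over all non-empty patterns sum to the
    size of the union.  The direction table covers the full intersection
    and flags whether log2FC has the same sign in every species.
    """
    if len(deg_sets) < 2:
        raise ValueError("need at least 2 DEG sets")
    names = [d.species for d in deg_sets]
    if len(set(names)) != len(names):
        raise ValueError("species labels must be unique")
    universe = set().union(*(d.symbols for d in deg_sets))
    regions: dict[str, int] = {}
    for r in range(1, len(deg_sets) + 1):
        for combo in combinations(range(len(deg_sets)), r):
            inside = set.intersection(*(deg_sets[i].symbols for i in combo))
            outside = set().union(
                *(deg_sets[i].symbols for i in range(len(deg_sets))
                  if i not in combo),
                set(),
            )
            exact = inside - outside
            key = "&".join(sorted(names[i] for i in combo))
            regions[key] = len(exact)
    core = set.intersection(*(d.symbols for d in deg_sets))
    rows = []
    for sym in sorted(core):
        lfcs = [d.entries[sym][0] for d in deg_sets]
        concordant = all(v > 0 for v in lfcs) or all(v < 0 for v in lfcs)
        row = {"symbol": sym, "concordant": concordant}
        for d in deg_sets:
            row[f"log2fc_{d.species}"] = d.entries[sym][0]
        rows.append(row)
    table = pd.DataFrame(rows)
    assert sum(regions.values()) == len(universe)
    return core, regions, table
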