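"""Cross-breed set logic: exclusive Venn partition and breed-specific sets.

A breed-specific SNP is a variant key present in exactly one breed's
filtered (fixed-SNP) set and absent from the filtered sets of every
other breed.  The Venn partition assigns each key of the union to the
single cell labelled by the exact subset of breeds containing it; for B
breeds there are 2^B - 1 potential cells and their counts sum to the
union size by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from breedsnp.vcf_io import VariantKey

__all__ = ["VennTable", "venn_partition", "breed_specific_sets"]


@dataclass
class VennTable:
    """Exclusive partition of the union of per-breed variant sets.

    ``cells`` maps a breed subset (frozenset of breed names) to the
    number of keys present in exactly those breeds.  Subsets whose cell
    is empty are omitted.
    """

    breeds: list[str]
    cells: dict[frozenset[str], int] = field(default_factory=dict)

    def count(self, *breeds: str) -> int:
        return self.cells.get(frozenset(breeds), 0)

    @property
    def total(self) -> int:
        return sum(self.cells.values())

    def to_rows(self) -> list[tuple[str, int]]:
        """Cells as (comma-joined subset label, count) rows, breeds in
        panel order, subsets ordered by size then label."""
        order = {b: i for i, b in enumerate(self.breeds)}
        rows = []
        for subset, count in self.cells.items():
            members = sorted(subset, key=order.get)
            rows.append((",".join(members), count, len(members)))
        rows.sort(key=lambda r: (r[2], r[0]))
        return [(label, count) for label, count, _ in rows]


def venn_partition(per_breed: Mapping[str, set[VariantKey]]) -> VennTable:
    """Partition the union of per-breed sets into exclusive Venn cells."""
    if len(per_breed) < 2:
        raise ValueError("venn_partition requires at least 2 breeds")
    membership: dict[VariantKey, set[str]] = {}
    for breed, keys in per_breed.items():
        for key in keys:
            membership.setdefault(key, set()).add(breed)
    table = VennTable(breeds=list(per_breed))
    for subset in map(frozenset, membership.values()):
        table.cells[subset] = table.cells.get(subset, 0) + 1
    return table


def breed_specific_sets(
    per_breed: Mapping[str, set[VariantKey]]
) -> dict[str, set[VariantKey]]:
    """Keys present in one breed's filtered set and no other's.

    Equals the singleton cells of :func:`venn_partition`.
    """
    specific: dict[str, set[VariantKey]] = {b: set() for b in per_breed}
    for breed, keys in per_breed.items():
        others: set[VariantKey] = set()
        for other, other_keys in per_breed.items():
            if other != breed:
                others |= other_keys
        specific[breed] = keys - others
    return specific
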