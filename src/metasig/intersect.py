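"""Gene-list intersection and direction-concordance summaries.

The integrative step of the pipeline: intersect a list of genes proximal to
tumor-specific transcription-factor binding sites with a knockdown DEG list
to obtain the candidate target panel, and characterize whether shared genes
move in the same or opposite directions in the two contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .data_model import DEGTable

__all__ = ["GeneList", "IntersectionReport", "intersect_gene_lists", "direction_concordance"]


def _normalize(genes) -> frozenset[str]:
    return frozenset(str(g).strip().upper() for g in genes if str(g).strip())


@dataclass(frozen=True)
class GeneList:
    """A named set of gene symbols, upper-cased and whitespace-stripped."""

    name: str
    genes: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes) -> "GeneList":
        return cls(name, _normalize(genes))

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "GeneList":
        """Read a one-symbol-per-line text file."""
        path = Path(path)
        lines = path.read_text().splitlines()
        return cls.from_iterable(name or path.stem, lines)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, g: str) -> bool:
        return str(g).strip().upper() in self.genes


@dataclass(frozen=True)
class IntersectionReport:
    intersection: GeneList
    size_a: int
    size_b: int
    size_intersection: int
    only_a: int
    only_b: int

    def to_dict(self) -> dict:
        return {
            "name": self.intersection.name,
            "size_a": self.size_a,
            "size_b": self.size_b,
            "size_intersection": self.size_intersection,
            "only_a": self.only_a,
            "only_b": self.only_b,
            "genes": sorted(self.intersection.genes),
        }


def intersect_gene_lists(a: GeneList, b: GeneList) -> IntersectionReport:
    """Set intersection of two gene lists with Venn-exclusive counts."""
    if not a.genes or not b.genes:
        raise ValueError("gene lists must be nonempty")
    inter = a.genes & b.genes
    return IntersectionReport(
        intersection=GeneList(f"{a.name}&{b.name}", frozenset(inter)),
        size_a=len(a.genes),
        size_b=len(b.genes),
        size_intersection=len(inter),
        only_a=len(a.genes - b.genes),
        only_b=len(b.genes - a.genes),
    )


def direction_concordance(a: DEGTable, b: DEGTable) -> dict:
    """Quadrant counts of up/down direction pairs over shared genes.

    Returns counts of (up,up), (up,down), (down,up), (down,down) plus the
    discordant fraction (opposite-direction pairs over shared genes).
    """
    shared = [g for g in a.genes if g in set(b.genes)]
    if not shared:
        raise ValueError("no shared genes between DEG tables")
    da = a.directions().loc[shared]
    db = b.directions().loc[shared]
    counts = {("up", "up"): 0, ("up", "down"): 0, ("down", "up"): 0, ("down", "down"): 0}
    for g in shared:
        counts[(da[g], db[g])] += 1
    discordant = counts[("up", "down")] + counts[("down", "up")]
    return {
        "n_shared": len(shared),
        "up_up": counts[("up", "up")],
        "up_down": counts[("up", "down")],
        "down_up": counts[("down", "up")],
        "down_down": counts[("down", "down")],
        "discordant_fraction": discordant / len(shared),
    }
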