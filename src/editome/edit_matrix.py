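"""Binary editing-site matrices for phylogenetic analysis.

All C-to-U positions observed in a gene across species form that gene's
editing template; concatenated templates define an ordered set of binary
characters, and each species is mapped onto them as a presence/absence row.
The matrix serializes to a MrBayes-compatible NEXUS DATA block.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .edit_predict import EditingProfile

__all__ = [
    "GeneTemplate",
    "BinaryEditingMatrix",
    "NexusError",
    "build_gene_template",
    "concatenate_templates",
    "build_binary_matrix",
    "write_nexus",
    "read_nexus",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneTemplate:
    """Sorted unique 1-based CDS positions edited in >=1 species of a gene."""

    gene: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.positions[1:], self.positions)):
            raise ValueError("template positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class BinaryEditingMatrix:
    """Taxa x (gene, position) presence/absence characters."""

    taxa: list[str]
    characters: list[tuple[str, int]]
    cells: np.ndarray  # shape (n_taxa, n_characters), dtype uint8
    direction: str = "C2U"

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.uint8)
        if self.cells.shape != (len(self.taxa), len(self.characters)):
            raise ValueError(
                f"cells shape {self.cells.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters"
            )

    @property
    def width(self) -> int:
        return len(self.characters)

    def row(self, taxon: str) -> np.ndarray:
        return self.cells[self.taxa.index(taxon)]

    def row_sums(self) -> dict[str, int]:
        return {t: int(self.cells[i].sum()) for i, t in enumerate(self.taxa)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryEditingMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.characters == other.characters
            and np.array_equal(self.cells, other.cells)
        )


def build_gene_template(profile: EditingProfile, gene: str, direction: str = "C2U") -> GeneTemplate:
    """Union of edited positions for one gene across all species, sorted."""
    positions: set[int] = set()
    present = False
    for sp in profile.species():
        if gene in profile.sites[sp]:
            present = True
            positions.update(
                s.position for s in profile.sites_for(sp, gene) if s.direction == direction
            )
    if not present:
        logger.warning("gene %s absent from every species; empty template", gene)
    return GeneTemplate(gene=gene, positions=tuple(sorted(positions)))


def concatenate_templates(
    templates: Mapping[str, GeneTemplate], gene_order: Sequence[str]
) -> list[tuple[str, int]]:
    """Concatenate gene templates into one ordered character-label list.

    Characters are ordered gene-major following ``gene_order``, then by
    position within each gene.
    """
    labels: list[tuple[str, int]] = []
    for gene in gene_order:
        if gene not in templates:
            raise ValueError(f"no template for gene {gene!r} in gene_order")
        labels.extend((gene, p) for p in templates[gene].positions)
    return labels


def build_binary_matrix(
    profile: EditingProfile,
    global_template: Sequence[tuple[str, int]],
    direction: str = "C2U",
    exclude: Iterable[str] = (),
) -> BinaryEditingMatrix:
    """Map each species' editing positions onto the concatenated template.

    ``exclude`` drops taxa (typically the prediction reference, which by
    construction has no sites and would carry no signal). Species whose
    sites include a position missing from the template raise, since that
    indicates the template was built from a different profile. All-zero
    rows are retained with a warning.
    """
    exclude = set(exclude)
    taxa = [sp for sp in profile.species() if sp not in exclude]
    index = {label: j for j, label in enumerate(global_template)}
    cells = np.zeros((len(taxa), len(global_template)), dtype=np.uint8)
    for i, sp in enumerate(taxa):
        for gene in profile.genes(sp):
            for site in profile.sites_for(sp, gene):
                if site.direction != direction:
                    continue
                key = (gene, site.position)
                if key not in index:
                    raise ValueError(
                        f"site {key} of species {sp!r} absent from template "
                        "(template/profile mismatch)"
                    )
                cells[i, index[key]] = 1
        if cells[i].sum() == 0:
            logger.warning("species %s has an all-zero character row", sp)
    return BinaryEditingMatrix(
        taxa=taxa, characters=list(global_template), cells=cells, direction=direction
    )


class NexusError(ValueError):
    """Malformed NEXUS input."""


def _quote(label: str) -> str:
    if re.search(r"[\s()\[\]{}/\\,;:=*'\"`+<>-]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_nexus(matrix: BinaryEditingMatrix) -> str:
    """Serialize to a MrBayes-compatible NEXUS DATA block.

    Character labels are emitted as CHARSTATELABELS ``gene_position`` so a
    roundtrip preserves the (gene, position) identity of every column.
    """
    if matrix.width == 0 or not matrix.taxa:
        raise ValueError("cannot serialize an empty matrix")
    out = io.StringIO()
    out.write("#NEXUS\n\nBEGIN DATA;\n")
    out.write(f"    DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.width};\n")
    out.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\n')
    labels = ", ".join(
        f"{j + 1} {_quote(f'{gene}_{pos}')}"
        for j, (gene, pos) in enumerate(matrix.characters)
    )
    out.write(f"    CHARSTATELABELS {labels};\n")
    out.write("    MATRIX\n")
    pad = max(len(_quote(t)) for t in matrix.taxa) + 2
    for i, taxon in enumerate(matrix.taxa):
        row = "".join(str(int(c)) for c in matrix.cells[i])
        out.write(f"    {_quote(taxon):<{pad}}{row}\n")
    out.write("    ;\nEND;\n")
    return out.getvalue()


_CHARLABEL_RE = re.compile(r"(\d+)\s+(?:'([^']+)'|(\S+?))\s*(?:,|;)")


def read_nexus(text: str) -> BinaryEditingMatrix:
    """Parse a binary NEXUS DATA block back into a matrix.

    The 0/1 matrix and taxon labels are parsed with dendropy; character
    labels of the form ``gene_position`` are recovered from the
    CHARSTATELABELS statement when present, otherwise synthesized as
    ``("char", column)``.
    """
    try:
        cm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises schema-specific errors
        line = getattr(exc, "line_num", None)
        where = f" at line {line}" if line else ""
        raise NexusError(f"NEXUS parse error{where}: {exc}") from exc
    taxa = [t.label for t in cm.taxon_namespace]
    rows = []
    for taxon in cm.taxon_namespace:
        rows.append([int(str(state)) for state in cm[taxon]])
    cells = np.asarray(rows, dtype=np.uint8)
    labels: list[tuple[str, int]] = []
    m = re.search(r"CHARSTATELABELS\s+(.*?);", text, flags=re.S | re.I)
    if m:
        for num, quoted, bare in _CHARLABEL_RE.findall(m.group(1) + ","):
            name = quoted or bare
            gene, _, pos = name.rpartition("_")
            try:
                labels.append((gene, int(pos)))
            except ValueError:
                labels.append((name, 0))
    if len(labels) != cells.shape[1]:
        labels = [("char", j + 1) for j in range(cells.shape[1])]
    return BinaryEditingMatrix(taxa=taxa, characters=labels, cells=cells)
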