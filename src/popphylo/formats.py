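"""MEGA and PHYLIP distance-matrix serialisation.

Both writers emit fixed-point values with six decimals so that re-parsing a
document recovers every entry at that precision.  MEGA uses the lower-left
triangular layout; PHYLIP uses the strict (original) dialect with names
padded or truncated to exactly ten characters.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .distance import DistanceMatrix
from .errors import ValidationError

__all__ = ["MatrixDialect", "MatrixDocument", "write_mega", "write_phylip"]

PHYLIP_NAME_WIDTH = 10


class MatrixDialect(Enum):
    MEGA = "mega"
    PHYLIP = "phylip"


@dataclass(frozen=True)
class MatrixDocument:
    dialect: MatrixDialect
    body: str


def _check_min_size(m: DistanceMatrix) -> None:
    if m.n < 2:
        raise ValidationError("a distance matrix needs at least two samples")


def write_mega(m: DistanceMatrix, title: str = "popphylo pairwise distances"
               ) -> MatrixDocument:
    """Lower-left triangular MEGA distance document.

    Header lines follow MEGA's distance-data grammar (``#mega``, ``!Title``,
    ``!Format``), then one ``#name`` line per taxon, then row i of the
    triangle listing d[i][0..i-1].
    """
    _check_min_size(m)
    if len(set(m.samples)) != m.n:
        raise ValidationError("duplicate sample names in distance matrix")
    lines = [
        "#mega",
        f"!Title {title};",
        f"!Format DataType=Distance DataFormat=LowerLeft NTaxa={m.n};",
        "",
    ]
    lines += [f"#{name}" for name in m.samples]
    lines.append("")
    for i in range(1, m.n):
        lines.append(" ".join(f"{m.values[i, j]:.6f}" for j in range(i)))
    return MatrixDocument(MatrixDialect.MEGA, "\n".join(lines) + "\n")


def write_phylip(m: DistanceMatrix) -> MatrixDocument:
    """Square PHYLIP distance document with strict 10-character names."""
    _check_min_size(m)
    padded = [name[:PHYLIP_NAME_WIDTH].ljust(PHYLIP_NAME_WIDTH)
              for name in m.samples]
    if len(set(padded)) != m.n:
        raise ValidationError(
            f"sample names collide after truncation to {PHYLIP_NAME_WIDTH} "
            "characters"
        )
    lines = [f"{m.n:>5}"]
    for i, name in enumerate(padded):
        row = " ".join(f"{m.values[i, j]:.6f}" for j in range(m.n))
        lines.append(f"{name} {row}")
    return MatrixDocument(MatrixDialect.PHYLIP, "\n".join(lines) + "\n")
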