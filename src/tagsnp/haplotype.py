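"""Haplotype-block data model, plain-text I/O and synthetic block generation.

The on-disk format is deliberately minimal: one haplotype pattern per line
as a string over ``{0,1}``, with optional ``#`` comment lines.  Two special
comment headers, ``# snp_ids:`` and ``# pattern_ids:``, carry optional
labels through a read/write round trip.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TextIO, Union

import numpy as np

__all__ = [
    "BlockFormatError",
    "BlockValidationError",
    "GenerationError",
    "HaplotypeBlock",
    "SyntheticBlockSpec",
    "distinguishability",
    "generate_block",
    "read_block",
    "write_block",
]


class BlockFormatError(ValueError):
    """Raised when a block file does not conform to the matrix format."""


class BlockValidationError(ValueError):
    """Raised when a parsed matrix violates a haplotype-block invariant."""


class GenerationError(RuntimeError):
    """Raised when the synthetic generator cannot satisfy its contract."""


def _default_snp_ids(n: int) -> list[str]:
    return [f"S{k + 1}" for k in range(n)]


def _default_pattern_ids(m: int) -> list[str]:
    return [f"P{i + 1}" for i in range(m)]


@dataclass(frozen=True)
class HaplotypeBlock:
    """An m x n binary matrix of distinct haplotype patterns over n SNPs.

    Parameters
    ----------
    matrix
        Array-like of shape ``(m, n)`` with entries in ``{0, 1}``.
    snp_ids
        Optional SNP labels; defaults to ``S1..Sn`` (1-based, user-facing).
    pattern_ids
        Optional pattern labels; defaults to ``P1..Pm``.

    Raises
    ------
    BlockValidationError
        If any entry is not 0/1, if ``m < 2`` or ``n < 1``, or if two rows
        are identical (allele classes must be distinct patterns).
    """

    matrix: np.ndarray
    snp_ids: tuple[str, ...] = field(default=())
    pattern_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix)
        if mat.ndim != 2:
            raise BlockValidationError(
                f"matrix must be 2-dimensional, got shape {mat.shape}"
            )
        if not np.isin(mat, (0, 1)).all():
            raise BlockValidationError("matrix entries must all be 0 or 1")
        mat = mat.astype(np.uint8)
        mat.setflags(write=False)
        object.__setattr__(self, "matrix", mat)
        m, n = mat.shape
        if m < 2:
            raise BlockValidationError(f"need at least 2 patterns, got {m}")
        if n < 1:
            raise BlockValidationError("need at least 1 SNP")
        seen: dict[bytes, int] = {}
        for i in range(m):
            key = mat[i].tobytes()
            if key in seen:
                raise BlockValidationError(
                    f"duplicate haplotype patterns at rows {seen[key] + 1} "
                    f"and {i + 1} (1-based): patterns must be distinct"
                )
            seen[key] = i
        snp_ids = tuple(self.snp_ids) or tuple(_default_snp_ids(n))
        pattern_ids = tuple(self.pattern_ids) or tuple(_default_pattern_ids(m))
        if len(snp_ids) != n:
            raise BlockValidationError(
                f"expected {n} snp_ids, got {len(snp_ids)}"
            )
        if len(pattern_ids) != m:
            raise BlockValidationError(
                f"expected {m} pattern_ids, got {len(pattern_ids)}"
            )
        object.__setattr__(self, "snp_ids", snp_ids)
        object.__setattr__(self, "pattern_ids", pattern_ids)

    @property
    def m(self) -> int:
        """Number of haplotype patterns (allele classes)."""
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        """Number of SNPs."""
        return self.matrix.shape[1]

    @classmethod
    def from_strings(cls, rows: Sequence[str], **kwargs) -> "HaplotypeBlock":
        """Build a block from pattern strings like ``["00101", "01100"]``."""
        parsed = []
        for i, row in enumerate(rows):
            bad = set(row) - {"0", "1"}
            if bad:
                raise BlockFormatError(
                    f"row {i + 1} contains characters outside {{0,1}}: {sorted(bad)}"
                )
            parsed.append([int(ch) for ch in row])
        lengths = {len(r) for r in parsed}
        if len(lengths) > 1:
            raise BlockFormatError(
                f"ragged rows: lengths {sorted(lengths)} differ"
            )
        return cls(np.array(parsed, dtype=np.uint8), **kwargs)

    def row_strings(self) -> list[str]:
        return ["".join(str(int(v)) for v in row) for row in self.matrix]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"HaplotypeBlock(m={self.m}, n={self.n})"


def read_block(source: Union[str, Path, TextIO], format: str = "matrix") -> HaplotypeBlock:
    """Read a haplotype block from a plain-text matrix file or stream.

    Each non-empty, non-comment line is one pattern over ``{0,1}``.  Comment
    lines start with ``#``; headers ``# snp_ids: a b c`` and
    ``# pattern_ids: x y`` restore labels, all other comments are ignored.
    """
    if format != "matrix":
        raise ValueError(f"unsupported format {format!r}")
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_block(fh, format=format)

    rows: list[str] = []
    snp_ids: tuple[str, ...] = ()
    pattern_ids: tuple[str, ...] = ()
    for raw in source:
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("snp_ids:"):
                snp_ids = tuple(body[len("snp_ids:"):].split())
            elif body.startswith("pattern_ids:"):
                pattern_ids = tuple(body[len("pattern_ids:"):].split())
            continue
        rows.append(line)
    if not rows:
        raise BlockFormatError("no data lines found")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise BlockFormatError(f"ragged lines: lengths {sorted(lengths)} differ")
    for i, row in enumerate(rows):
        bad = set(row) - {"0", "1"}
        if bad:
            raise BlockFormatError(
                f"line {i + 1} contains characters outside {{0,1}}: {sorted(bad)}"
            )
    matrix = np.array([[int(ch) for ch in row] for row in rows], dtype=np.uint8)
    return HaplotypeBlock(matrix, snp_ids=snp_ids, pattern_ids=pattern_ids)


def write_block(block: HaplotypeBlock, sink: Union[str, Path, TextIO]) -> None:
    """Write ``block`` in the matrix format accepted by :func:`read_block`.

    Labels are emitted as ``#``-prefixed header lines so that a round trip
    preserves them; the matrix itself round-trips exactly.
    """
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            write_block(block, fh)
        return
    sink.write("# snp_ids: " + " ".join(block.snp_ids) + "\n")
    sink.write("# pattern_ids: " + " ".join(block.pattern_ids) + "\n")
    for row in block.row_strings():
        sink.write(row + "\n")


def block_to_string(block: HaplotypeBlock) -> str:
    """Serialize a block to the matrix format as a string."""
    buf = io.StringIO()
    write_block(block, buf)
    return buf.getvalue()


def distinguishability(block: HaplotypeBlock) -> np.ndarray:
    """Per-SNP count of unordered pattern pairs the SNP distinguishes.

    For column k with ``z`` zeros among ``m`` rows the count is ``z*(m-z)``:
    exactly the pairs whose alleles differ at that SNP.  Bounded by
    ``floor(m/2)*ceil(m/2)``; a constant column scores 0.
    """
    zeros = (block.matrix == 0).sum(axis=0)
    return (zeros * (block.m - zeros)).astype(np.int64)


@dataclass(frozen=True)
class SyntheticBlockSpec:
    """Parameters for the founder/recombination synthetic block generator.

    Patterns are derived from ``n_founders`` random binary founder rows by
    walking across SNPs and switching founders with probability
    ``recomb_rate``, then flipping each allele with probability
    ``noise_rate``.  This induces the column correlation (LD-like structure)
    real blocks exhibit; i.i.d. columns are recovered with
    ``noise_rate=0.5``.
    """

    m: int
    n: int
    n_founders: int = 3
    recomb_rate: float = 0.02
    noise_rate: float = 0.02
    seed: int = 0
    forbid_constant_columns: bool = False

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"m must be >= 2, got {self.m}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 1 <= self.n_founders <= self.m:
            raise ValueError(
                f"n_founders must be in [1, m={self.m}], got {self.n_founders}"
            )
        for name in ("recomb_rate", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


_MAX_ROW_RETRIES = 200


def _derive_pattern(founders: np.ndarray, recomb: float, noise: float,
                    rng: np.random.Generator) -> np.ndarray:
    """One pattern: founder copying with per-SNP switching, then noise."""
    k, n = founders.shape
    if k == 1 or recomb <= 0.0:
        idx = np.full(n, rng.integers(k))
    else:
        switch = rng.random(n - 1) < recomb
        idx = np.empty(n, dtype=np.int64)
        idx[0] = rng.integers(k)
        cur = idx[0]
        for j, sw in enumerate(switch, start=1):
            if sw:
                cur = rng.integers(k)
            idx[j] = cur
    row = founders[idx, np.arange(n)].copy()
    if noise > 0.0:
        flips = rng.random(n) < noise
        row[flips] ^= 1
    return row


def generate_block(spec: SyntheticBlockSpec) -> HaplotypeBlock:
    """Generate a valid synthetic block; pure function of ``spec``.

    Raises
    ------
    GenerationError
        If ``m`` distinct rows cannot be produced within the retry budget
        (e.g. ``m > 2**n``).
    """
    rng = np.random.default_rng(spec.seed)
    founders = rng.integers(0, 2, size=(spec.n_founders, spec.n), dtype=np.uint8)
    rows: list[np.ndarray] = []
    seen: set[bytes] = set()
    for _ in range(spec.m):
        for _attempt in range(_MAX_ROW_RETRIES):
            row = _derive_pattern(founders, spec.recomb_rate, spec.noise_rate, rng)
            key = row.tobytes()
            if key not in seen:
                seen.add(key)
                rows.append(row)
                break
        else:
            raise GenerationError(
                f"could not generate {spec.m} distinct patterns of length "
                f"{spec.n} within {_MAX_ROW_RETRIES} retries per row"
            )
    matrix = np.array(rows, dtype=np.uint8)

    if spec.forbid_constant_columns:
        for _attempt in range(_MAX_ROW_RETRIES):
            const = matrix.min(axis=0) == matrix.max(axis=0)
            if not const.any():
                break
            # Redraw constant columns i.i.d.; may collide rows, so re-check.
            matrix[:, const] = rng.integers(
                0, 2, size=(spec.m, int(const.sum())), dtype=np.uint8
            )
            if len({r.tobytes() for r in matrix}) < spec.m:
                # A redraw merged two rows: restart those columns next loop
                # by forcing them constant-checked again via full redraw.
                matrix[:, const] = rng.integers(
                    0, 2, size=(spec.m, int(const.sum())), dtype=np.uint8
                )
        const = matrix.min(axis=0) == matrix.max(axis=0)
        dup = len({r.tobytes() for r in matrix}) < spec.m
        if const.any() or dup:
            raise GenerationError(
                "could not remove constant columns while keeping rows distinct"
            )

    return HaplotypeBlock(matrix)
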