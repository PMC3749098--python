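"""Abundance census coding: domain-by-proteome counts to ordered multistate characters.

A genomic census records the abundance ``g`` of each protein-domain
structure (SCOP-style fold, superfamily or family identifiers such as
``c.26.1.1``) in each sampled proteome.  For phylogenetic reconstruction
each proteome column is converted into a linearly ordered multistate
character: abundances are rescaled to [0, 1] against the column maximum
(optionally after a ``ln(g+1)`` transform) and discretized into ``S``
equal-width ordered bins.  Character states therefore preserve the rank
order of abundances within a proteome, which is the polarization signal
the reconstruction relies on.

States are written with the alphabet ``0-9`` then ``A-N`` (up to 24
states), the convention used for published abundance matrices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

#: Character-state alphabet: 0-9 then A-N, supporting up to 24 ordered states.
STATE_ALPHABET = "0123456789ABCDEFGHIJKLMN"

DEFAULT_N_STATES = 24


class MatrixFormatError(ValueError):
    """Raised when a character-matrix file cannot be parsed."""


@dataclass
class AbundanceMatrix:
    """Domain x proteome table of nonnegative genomic abundance counts."""

    domain_ids: list[str]
    proteome_ids: list[str]
    g: np.ndarray  # (n_domains, n_proteomes), nonnegative integers

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g)
        if self.g.ndim != 2:
            raise ValueError("abundance matrix must be 2-D")
        if self.g.shape != (len(self.domain_ids), len(self.proteome_ids)):
            raise ValueError(
                f"matrix shape {self.g.shape} does not match "
                f"{len(self.domain_ids)} domains x {len(self.proteome_ids)} proteomes"
            )
        if (self.g < 0).any():
            raise ValueError("abundance counts must be nonnegative")
        if len(set(self.domain_ids)) != len(self.domain_ids):
            raise ValueError("domain ids must be unique")
        if len(set(self.proteome_ids)) != len(self.proteome_ids):
            raise ValueError("proteome ids must be unique")


@dataclass
class CharacterMatrix:
    """Taxa x characters matrix of linearly ordered multistate characters.

    ``states[i, j]`` is the state (0..n_states-1) of taxon ``i`` for
    character ``j``.  ``ancestor`` optionally holds the state vector of a
    hypothetical ancestor used for Lundberg rooting.
    """

    taxa: list[str]
    n_states: int
    states: np.ndarray
    ancestor: np.ndarray | None = None
    ordering: str = "linear-ordered"

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.ndim != 2 or self.states.shape[0] != len(self.taxa):
            raise ValueError("states must be 2-D with one row per taxon")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.n_states > len(STATE_ALPHABET):
            raise ValueError(f"n_states must be <= {len(STATE_ALPHABET)}")
        if self.states.size and (self.states.min() < 0 or self.states.max() >= self.n_states):
            raise ValueError("state out of range 0..n_states-1")
        if self.ancestor is not None:
            self.ancestor = np.asarray(self.ancestor, dtype=int)
            if self.ancestor.shape != (self.states.shape[1],):
                raise ValueError("ancestor length must equal character count")

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]


def encode_characters(
    m: AbundanceMatrix,
    n_states: int = DEFAULT_N_STATES,
    transform: str = "linear",
    per_column: bool = True,
) -> CharacterMatrix:
    """Discretize an abundance matrix into ordered multistate characters.

    Each proteome column (or, with ``per_column=False``, the whole matrix)
    is rescaled by its maximum to [0, 1] — after ``ln(g+1)`` when
    ``transform='log'`` — and binned into ``n_states`` half-open
    equal-width bins; the top bin is closed so a value of exactly 1 maps
    to state ``n_states - 1``.  All-zero columns map to state 0.

    Parameters
    ----------
    m
        The abundance census.
    n_states
        Number of ordered character states S (>= 2); state symbols are
        0-9 then A-N so S may be at most 24.
    transform
        ``'linear'`` uses raw counts; ``'log'`` uses ln(g+1), which
        compresses the heavy upper tail of abundance distributions.
    per_column
        Normalize each proteome column by its own maximum (default) or by
        the global matrix maximum.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if transform not in ("linear", "log"):
        raise ValueError(f"unknown transform {transform!r}")
    if m.g.size == 0:
        raise ValueError("abundance matrix is empty")

    x = m.g.astype(float)
    if transform == "log":
        x = np.log1p(x)
    if per_column:
        colmax = x.max(axis=0)
        safe = np.where(colmax > 0, colmax, 1.0)
        scaled = x / safe
    else:
        gmax = x.max()
        scaled = x / gmax if gmax > 0 else x
    states = np.minimum((scaled * n_states).astype(int), n_states - 1)
    return CharacterMatrix(taxa=list(m.domain_ids), n_states=n_states, states=states)


# ---------------------------------------------------------------------------
# File formats

_ANCESTOR_LABEL = "__ancestor__"


def state_to_symbol(state: int) -> str:
    return STATE_ALPHABET[state]


def symbol_to_state(symbol: str) -> int:
    idx = STATE_ALPHABET.find(symbol.upper())
    if idx < 0:
        raise MatrixFormatError(f"state symbol {symbol!r} outside alphabet 0-9A-N")
    return idx


def write_matrix(m: CharacterMatrix, path, format: str = "tsv") -> None:
    """Write a character matrix as TSV or a NEXUS characters block."""
    if format == "tsv":
        _write_tsv(m, path)
    elif format == "nexus":
        _write_nexus(m, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_matrix(path, format: str = "tsv") -> CharacterMatrix:
    """Read a character matrix written by :func:`write_matrix`."""
    if format == "tsv":
        return _read_tsv(path)
    if format == "nexus":
        return _read_nexus(path)
    raise ValueError(f"unknown format {format!r}")


def _rows_with_ancestor(m: CharacterMatrix):
    rows = [(t, m.states[i]) for i, t in enumerate(m.taxa)]
    if m.ancestor is not None:
        rows.append((_ANCESTOR_LABEL, m.ancestor))
    return rows


def _write_tsv(m: CharacterMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#n_states\t{m.n_states}\n")
        for name, row in _rows_with_ancestor(m):
            symbols = "".join(state_to_symbol(s) for s in row)
            fh.write(f"{name}\t{symbols}\n")


def _read_tsv(path) -> CharacterMatrix:
    taxa: list[str] = []
    rows: list[list[int]] = []
    ancestor = None
    n_states = DEFAULT_N_STATES
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#n_states"):
                n_states = int(line.split("\t")[1])
                continue
            try:
                name, symbols = line.split("\t")
            except ValueError as exc:
                raise MatrixFormatError(f"line {lineno}: expected 'name<TAB>states'") from exc
            try:
                states = [symbol_to_state(c) for c in symbols]
            except MatrixFormatError as exc:
                raise MatrixFormatError(f"line {lineno}: {exc}") from exc
            if rows and len(states) != len(rows[0]):
                raise MatrixFormatError(f"line {lineno} (row {len(rows)}): ragged row length")
            if name == _ANCESTOR_LABEL:
                ancestor = states
            else:
                taxa.append(name)
                rows.append(states)
    if not rows:
        raise MatrixFormatError("no data rows found")
    return CharacterMatrix(taxa=taxa, n_states=n_states,
                           states=np.array(rows), ancestor=ancestor)


def _write_nexus(m: CharacterMatrix, path) -> None:
    rows = _rows_with_ancestor(m)
    width = max(len(name) for name, _ in rows) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\n")
        fh.write("BEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(rows)} NCHAR={m.n_characters};\n")
        fh.write(
            f"  FORMAT SYMBOLS=\"{STATE_ALPHABET[:m.n_states]}\" ORD;\n"
        )
        fh.write("  MATRIX\n")
        for name, row in rows:
            symbols = "".join(state_to_symbol(s) for s in row)
            fh.write(f"    {name:<{width}}{symbols}\n")
        fh.write("  ;\nEND;\n")


def _read_nexus(path) -> CharacterMatrix:
    with open(path) as fh:
        text = fh.read()
    sym = re.search(r'SYMBOLS\s*=\s*"([^"]+)"', text, re.I)
    n_states = len(sym.group(1)) if sym else DEFAULT_N_STATES
    matrix = re.search(r"MATRIX\s*\n(.*?)^\s*;", text, re.M | re.S | re.I)
    if matrix is None:
        raise MatrixFormatError("no MATRIX block found")
    taxa: list[str] = []
    rows: list[list[int]] = []
    ancestor = None
    for lineno, line in enumerate(matrix.group(1).splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise MatrixFormatError(f"matrix line {lineno}: expected 'name states'")
        name, symbols = parts
        try:
            states = [symbol_to_state(c) for c in symbols]
        except MatrixFormatError as exc:
            raise MatrixFormatError(f"matrix line {lineno}: {exc}") from exc
        if rows and len(states) != len(rows[0]):
            raise MatrixFormatError(f"matrix line {lineno}: ragged row length")
        if name == _ANCESTOR_LABEL:
            ancestor = states
        else:
            taxa.append(name)
            rows.append(states)
    if not rows:
        raise MatrixFormatError("empty MATRIX block")
    return CharacterMatrix(taxa=taxa, n_states=n_states,
                           states=np.array(rows), ancestor=ancestor)
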