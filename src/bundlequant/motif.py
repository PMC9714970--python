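"""Physicochemical-alphabet patterns and cholesterol-recognition motifs.

Degenerate patterns are written position-wise over a residue-class
alphabet (normalised symbols): Ω aromatic {F,W,Y,H}, Ψ aliphatic
{I,L,V,M}, π small {A,G,P,S}, ζ hydrophilic {D,E,H,K,N,Q,R,S,T},
Φ hydrophobic {A,C,F,I,L,M,V,W,Y}, + basic {K,R,H}, − acidic {D,E}.
The text syntax is PROSITE-like, positions joined by ``-``:

    literal residue          S
    explicit residue set     [ST]
    class symbol             Ω, or its ASCII name in brackets: [Omega]
    wildcard                 x
    variable gap             x(2,5)  (matches 2–5 arbitrary residues)

Conserved patterns are derived column-wise from alignments (literal →
explicit set → smallest covering class → wildcard), and sequences are
scanned for all (including overlapping) matches with 1-based inclusive
coordinates.  Cholesterol-recognition consensus motifs are special
cases: CRAC = (L/V)-x(1,5)-Y-x(1,5)-(K/R) read N→C and its mirrored
analogue CARC = (K/R)-x(1,5)-(Y/F/W)-x(1,5)-(L/V).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "AMINO_ACIDS",
    "ResidueClassTable",
    "DEFAULT_CLASSES",
    "classify_residue",
    "Position",
    "PatternExpr",
    "parse_pattern",
    "MotifMatch",
    "ConservedPatternMiner",
    "derive_pattern",
    "PatternScanner",
    "scan_pattern",
    "CracCarcScanner",
    "scan_crac_carc",
    "match_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ASCII aliases accepted in the text syntax for each class symbol
_CLASS_ALIASES = {
    "Omega": "Ω",
    "Psi": "Ψ",
    "pi": "π",
    "zeta": "ζ",
    "Phi": "Φ",
    "plus": "+",
    "minus": "-",
}
_SYMBOL_TO_ALIAS = {v: k for k, v in _CLASS_ALIASES.items()}


@dataclass(frozen=True)
class ResidueClassTable:
    """Mapping from class symbol to residue set (config-overridable).

    Every standard residue must belong to at least one class.
    """

    classes: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        covered: set[str] = set()
        for symbol, members in self.classes.items():
            if not members:
                raise ValueError(f"class {symbol!r} is empty")
            bad = set(members) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"class {symbol!r} contains non-residues {sorted(bad)}")
            covered |= set(members)
        missing = set(AMINO_ACIDS) - covered
        if missing:
            raise ValueError(f"residues {sorted(missing)} belong to no class")

    def __getitem__(self, symbol: str) -> frozenset[str]:
        return self.classes[symbol]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.classes

    def symbols(self) -> list[str]:
        return list(self.classes)

    def smallest_containing(self, residues: Iterable[str]) -> str | None:
        """Smallest class covering all residues (ties: table order); None if none."""
        rset = set(residues)
        best = None
        for symbol, members in self.classes.items():
            if rset <= members and (best is None or len(members) < len(self.classes[best])):
                best = symbol
        return best


DEFAULT_CLASSES = ResidueClassTable(
    {
        "Ω": frozenset("FWYH"),
        "Ψ": frozenset("ILVM"),
        "π": frozenset("AGPS"),
        "+": frozenset("KRH"),
        "-": frozenset("DE"),
        "ζ": frozenset("DEHKNQRST"),
        "Φ": frozenset("ACFILMVWY"),
    }
)


def classify_residue(
    residue: str, table: ResidueClassTable = DEFAULT_CLASSES, permissive: bool = False
) -> list[str]:
    """All class symbols containing the residue, in table order."""
    r = residue.upper()
    if r not in AMINO_ACIDS:
        if permissive:
            return []
        raise ValueError(f"unknown residue code {residue!r}")
    return [s for s, members in table.classes.items() if r in members]


@dataclass(frozen=True)
class Position:
    """One pattern position.

    ``kind`` is "literal", "set", "class", "wildcard" or "gap".  For
    matchable kinds ``allowed`` is the residue set; a gap spans ``m``–``n``
    arbitrary residues.
    """

    kind: str
    allowed: frozenset[str] = frozenset()
    symbol: str = ""
    m: int = 1
    n: int = 1

    def matches(self, residue: str) -> bool:
        if self.kind in ("wildcard", "gap"):
            return residue in AMINO_ACIDS
        return residue in self.allowed


@dataclass(frozen=True)
class PatternExpr:
    """Ordered degenerate pattern positions plus the class table used."""

    positions: tuple[Position, ...]
    table: ResidueClassTable = DEFAULT_CLASSES

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def min_width(self) -> int:
        return sum(p.m if p.kind == "gap" else 1 for p in self.positions)

    def to_text(self, ascii_names: bool = True) -> str:
        parts = []
        for p in self.positions:
            if p.kind == "literal":
                parts.append(next(iter(p.allowed)))
            elif p.kind == "set":
                parts.append("[" + "".join(sorted(p.allowed)) + "]")
            elif p.kind == "class":
                sym = p.symbol
                if ascii_names and sym in _SYMBOL_TO_ALIAS:
                    parts.append(f"[{_SYMBOL_TO_ALIAS[sym]}]")
                else:
                    parts.append(sym)
            elif p.kind == "wildcard":
                parts.append("x")
            else:
                parts.append(f"x({p.m},{p.n})")
        return "-".join(parts)


_GAP_RE = re.compile(r"^x\((\d+)(?:,(\d+))?\)$")


def parse_pattern(text: str, table: ResidueClassTable = DEFAULT_CLASSES) -> PatternExpr:
    """Parse the PROSITE-like text syntax; errors name the bad token."""
    tokens = _tokenize(text)
    positions: list[Position] = []
    for i, tok in enumerate(tokens):
        pos = _parse_token(tok, table)
        if pos is None:
            raise ValueError(f"pattern position {i + 1}: cannot parse token {tok!r}")
        positions.append(pos)
    if not positions:
        raise ValueError("empty pattern")
    return PatternExpr(tuple(positions), table)


def _tokenize(text: str) -> list[str]:
    """Split on '-' separators.  The acidic class must be written
    ``[minus]`` (a bare '-' is always a separator)."""
    raw = text.strip()
    if not raw:
        raise ValueError("empty pattern")
    tokens = raw.split("-")
    for i, tok in enumerate(tokens):
        if tok == "":
            raise ValueError(
                f"pattern position {i + 1}: empty token — write the acidic "
                "class as [minus], not a bare '-'"
            )
    return tokens


def _parse_token(tok: str, table: ResidueClassTable) -> Position | None:
    if tok == "x":
        return Position("wildcard")
    gm = _GAP_RE.match(tok)
    if gm:
        m = int(gm.group(1))
        n = int(gm.group(2)) if gm.group(2) is not None else m
        if not 0 <= m <= n:
            raise ValueError(f"gap bounds must satisfy 0 <= m <= n, got {tok!r}")
        return Position("gap", m=m, n=n)
    if tok.startswith("[") and tok.endswith("]"):
        inner = tok[1:-1]
        if inner in _CLASS_ALIASES and _CLASS_ALIASES[inner] in table:
            sym = _CLASS_ALIASES[inner]
            return Position("class", table[sym], symbol=sym)
        if inner in table:
            return Position("class", table[inner], symbol=inner)
        if inner and all(c in AMINO_ACIDS for c in inner.upper()):
            s = frozenset(inner.upper())
            if len(s) == 1:
                return Position("literal", s)
            return Position("set", s)
        return None
    if tok in table:
        return Position("class", table[tok], symbol=tok)
    if tok in _CLASS_ALIASES and _CLASS_ALIASES[tok] in table:
        sym = _CLASS_ALIASES[tok]
        return Position("class", table[sym], symbol=sym)
    if len(tok) == 1 and tok.upper() in AMINO_ACIDS:
        return Position("literal", frozenset(tok.upper()))
    return None


@dataclass(frozen=True)
class MotifMatch:
    """One pattern hit; coordinates are 1-based inclusive."""

    sequence_id: str
    start: int
    end: int
    matched: str
    kind: str = "pattern"


# ---------------------------------------------------------------------------
# Pattern derivation from alignments


class ConservedPatternMiner(BaseEstimator):
    """Column-wise derivation of conserved patterns from an alignment.

    Per column: a literal when one residue's frequency ≥
    ``min_literal_frac``; else an explicit set when the number of distinct
    residues ≤ ``max_set_size``; else the smallest residue class covering
    all residues; else a wildcard.  Columns with > ``max_gap_frac`` gaps
    are wildcards; other columns ignore gap characters.  Maximal windows
    of non-wildcard columns of length ≥ ``min_window_len`` become the
    fitted ``patterns_``.
    """

    def __init__(
        self,
        min_literal_frac: float = 0.9,
        max_set_size: int = 2,
        min_window_len: int = 4,
        max_gap_frac: float = 0.5,
        table: ResidueClassTable = DEFAULT_CLASSES,
    ):
        self.min_literal_frac = min_literal_frac
        self.max_set_size = max_set_size
        self.min_window_len = min_window_len
        self.max_gap_frac = max_gap_frac
        self.table = table

    def fit(self, alignment: Sequence[str], y=None):
        rows = [str(r).upper() for r in alignment]
        if not rows:
            raise ValueError("empty alignment")
        length = len(rows[0])
        if length == 0 or any(len(r) != length for r in rows):
            raise ValueError("alignment rows must be non-empty and equal-length")
        columns: list[Position] = []
        for j in range(length):
            col = [r[j] for r in rows]
            columns.append(self._column_position(col))
        self.column_positions_ = tuple(columns)
        self.patterns_ = self._windows(columns)
        return self

    def _column_position(self, col: list[str]) -> Position:
        gaps = sum(1 for c in col if c in "-.")
        if gaps / len(col) > self.max_gap_frac:
            return Position("wildcard")
        residues = [c for c in col if c in AMINO_ACIDS]
        if not residues:
            return Position("wildcard")
        counts = Counter(residues)
        res, freq = counts.most_common(1)[0]
        if freq / len(residues) >= self.min_literal_frac:
            return Position("literal", frozenset(res))
        distinct = frozenset(counts)
        if len(distinct) <= self.max_set_size:
            return Position("set", distinct)
        symbol = self.table.smallest_containing(distinct)
        if symbol is not None:
            return Position("class", self.table[symbol], symbol=symbol)
        return Position("wildcard")

    def _windows(self, columns: list[Position]) -> list[PatternExpr]:
        patterns = []
        start = None
        for j, pos in enumerate(columns + [Position("wildcard")]):
            if pos.kind != "wildcard":
                if start is None:
                    start = j
            elif start is not None:
                if j - start >= self.min_window_len:
                    patterns.append(
                        PatternExpr(tuple(columns[start:j]), self.table)
                    )
                start = None
        return patterns


def derive_pattern(
    alignment: Sequence[str],
    min_literal_frac: float = 0.9,
    max_set_size: int = 2,
    min_window_len: int = 4,
    table: ResidueClassTable = DEFAULT_CLASSES,
) -> list[PatternExpr]:
    """Functional wrapper over :class:`ConservedPatternMiner`."""
    miner = ConservedPatternMiner(
        min_literal_frac=min_literal_frac,
        max_set_size=max_set_size,
        min_window_len=min_window_len,
        table=table,
    )
    return miner.fit(alignment).patterns_


# ---------------------------------------------------------------------------
# Scanning


def _match_from(seq: str, start: int, positions: tuple[Position, ...], pi: int) -> list[int]:
    """All end offsets (exclusive) of matches of positions[pi:] at seq[start:]."""
    if pi == len(positions):
        return [start]
    pos = positions[pi]
    ends: list[int] = []
    if pos.kind == "gap":
        for g in range(pos.m, pos.n + 1):
            if start + g > len(seq):
                break
            if all(seq[start + t] in AMINO_ACIDS for t in range(g)):
                ends.extend(_match_from(seq, start + g, positions, pi + 1))
    else:
        if start < len(seq) and pos.matches(seq[start]):
            ends.extend(_match_from(seq, start + 1, positions, pi + 1))
    return ends


class PatternScanner(BaseEstimator):
    """Scan sequences for all (including overlapping) pattern matches."""

    def __init__(self, pattern: PatternExpr | str, kind: str = "pattern"):
        self.pattern = pattern
        self.kind = kind

    def _expr(self) -> PatternExpr:
        if isinstance(self.pattern, PatternExpr):
            return self.pattern
        return parse_pattern(self.pattern)

    def fit(self, X=None, y=None):
        return self

    def transform(
        self, sequences: Mapping[str, str] | Sequence[tuple[str, str]] | Sequence[str]
    ) -> list[MotifMatch]:
        expr = self._expr()
        matches: list[MotifMatch] = []
        for seq_id, seq in _iter_sequences(sequences):
            seq = seq.upper()
            seen: set[tuple[int, int]] = set()
            for start in range(len(seq) - expr.min_width + 1):
                for end in _match_from(seq, start, expr.positions, 0):
                    span = (start + 1, end)  # 1-based inclusive
                    if span not in seen:
                        seen.add(span)
                        matches.append(
                            MotifMatch(seq_id, span[0], span[1], seq[start:end], self.kind)
                        )
        matches.sort(key=lambda m: (m.sequence_id, m.start, m.end))
        return matches


def scan_pattern(
    pattern: PatternExpr | str,
    sequences: Mapping[str, str] | Sequence[tuple[str, str]] | Sequence[str],
) -> list[MotifMatch]:
    """Functional wrapper over :class:`PatternScanner`."""
    return PatternScanner(pattern).transform(sequences)


def _iter_sequences(sequences) -> list[tuple[str, str]]:
    if isinstance(sequences, Mapping):
        return [(str(k), str(v)) for k, v in sequences.items()]
    if isinstance(sequences, str):
        return [("seq0", sequences)]
    out = []
    for i, item in enumerate(sequences):
        if isinstance(item, tuple):
            out.append((str(item[0]), str(item[1])))
        elif hasattr(item, "id") and hasattr(item, "seq"):  # Bio.SeqRecord
            out.append((str(item.id), str(item.seq)))
        else:
            out.append((f"seq{i}", str(item)))
    return out


class CracCarcScanner(BaseEstimator):
    """Cholesterol-recognition consensus motif scanner.

    CRAC, read N→C: (L/V)-x(m,n)-Y-x(m,n)-(K/R); CARC is the mirrored
    analogue (K/R)-x(m,n)-(Y/F/W)-x(m,n)-(L/V).  Default spacing (1, 5).
    The aromatic centres are configurable; the strict consensus restricts
    CRAC to tyrosine while CARC tolerates Y/F/W.
    """

    def __init__(
        self,
        spacing: tuple[int, int] = (1, 5),
        crac_center: str = "Y",
        carc_center: str = "YFW",
    ):
        self.spacing = spacing
        self.crac_center = crac_center
        self.carc_center = carc_center

    def _patterns(self) -> list[tuple[str, PatternExpr]]:
        m, n = self.spacing
        if not 0 <= m <= n:
            raise ValueError(f"spacing must satisfy 0 <= m <= n, got {self.spacing}")
        gap = Position("gap", m=m, n=n)
        crac = PatternExpr(
            (
                Position("set", frozenset("LV")),
                gap,
                Position("set", frozenset(self.crac_center.upper())),
                gap,
                Position("set", frozenset("KR")),
            )
        )
        carc = PatternExpr(
            (
                Position("set", frozenset("KR")),
                gap,
                Position("set", frozenset(self.carc_center.upper())),
                gap,
                Position("set", frozenset("LV")),
            )
        )
        return [("CRAC", crac), ("CARC", carc)]

    def fit(self, X=None, y=None):
        return self

    def transform(self, sequences) -> list[MotifMatch]:
        matches: list[MotifMatch] = []
        for kind, expr in self._patterns():
            matches.extend(PatternScanner(expr, kind=kind).transform(sequences))
        matches.sort(key=lambda m: (m.sequence_id, m.start, m.end, m.kind))
        return matches


def scan_crac_carc(
    sequence_or_sequences, spacing: tuple[int, int] = (1, 5)
) -> list[MotifMatch]:
    """Functional wrapper over :class:`CracCarcScanner`."""
    return CracCarcScanner(spacing=spacing).transform(sequence_or_sequences)


def match_table(matches: Iterable[MotifMatch]) -> pd.DataFrame:
    """Matches as a BED-like table with 1-based inclusive coordinates."""
    rows = [
        {"seq_id": m.sequence_id, "start": m.start, "end": m.end, "kind": m.kind,
         "span": m.matched}
        for m in matches
    ]
    return pd.DataFrame(rows, columns=["seq_id", "start", "end", "kind", "span"])
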