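"""Sequence, alignment and secondary-structure I/O.

Reads FASTA and Stockholm 1.0 (Rfam-seed style, with the ``#=GC SS_cons``
consensus-structure line), parses dot-bracket strings, converts reference
multiple alignments into pairwise training instances and annotates each
sequence position with its secondary-substructure class.

Conventions used throughout the package:

* positions are 1-based and inclusive;
* RNA residues are normalised to uppercase {A, C, G, U} (T becomes U);
* ``.`` and ``-`` are both gap characters on read, ``-`` is written.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

from Bio import AlignIO, SeqIO

__all__ = [
    "RnaSequence",
    "MultipleAlignment",
    "PairwiseAlignment",
    "SecondaryStructure",
    "SUBSTRUCTURE_LABELS",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_stockholm",
    "write_stockholm",
    "extract_pairwise",
    "parse_dotbracket",
    "annotate_substructures",
]

GAP_CHARS = {".", "-"}
_VALID = set("ACGU")

#: the six secondary-substructure classes a position can belong to
SUBSTRUCTURE_LABELS = (
    "stem-pair",
    "hairpin-loop",
    "bulge-or-internal-loop",
    "multibranch-loop",
    "external-5prime",
    "external-3prime",
)


class FormatError(ValueError):
    """Raised for malformed FASTA/Stockholm/dot-bracket input."""


def normalize_residues(raw: str) -> str:
    return raw.upper().replace("T", "U")


@dataclass(frozen=True)
class RnaSequence:
    """An ncRNA sequence with a normalised residue string."""

    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError(f"empty sequence {self.id!r}")
        bad = set(self.residues) - _VALID
        if bad:
            raise ValueError(f"sequence {self.id!r} contains {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PairwiseAlignment:
    """Ordered alignment columns: (i, j) matches and (i, None)/(None, j) gaps.

    The i indices are strictly increasing and cover 1..n exactly once;
    likewise j over 1..m.
    """

    columns: list[tuple[int | None, int | None]]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        iseq = [i for i, _ in self.columns if i is not None]
        jseq = [j for _, j in self.columns if j is not None]
        if any(i is None and j is None for i, j in self.columns):
            raise ValueError("(-,-) column in alignment")
        if iseq != list(range(1, len(iseq) + 1)):
            raise ValueError("i indices must increase and cover 1..n")
        if jseq != list(range(1, len(jseq) + 1)):
            raise ValueError("j indices must increase and cover 1..m")

    @property
    def n(self) -> int:
        return sum(1 for i, _ in self.columns if i is not None)

    @property
    def m(self) -> int:
        return sum(1 for _, j in self.columns if j is not None)

    def matched_pairs(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j in self.columns if i is not None and j is not None}

    def to_gapped(self, a: str, b: str) -> tuple[str, str]:
        """Render the two aligned rows as gapped strings."""
        ra, rb = [], []
        for i, j in self.columns:
            ra.append(a[i - 1] if i is not None else "-")
            rb.append(b[j - 1] if j is not None else "-")
        return "".join(ra), "".join(rb)


@dataclass
class MultipleAlignment:
    """Aligned family rows plus an optional consensus structure string."""

    rows: list[tuple[str, str]]
    ss_cons: str | None = None

    def __post_init__(self):
        lens = {len(s) for _, s in self.rows}
        if len(lens) > 1:
            raise FormatError("alignment rows have unequal length")
        if self.ss_cons is not None and self.rows and len(self.ss_cons) != self.n_columns:
            raise FormatError("SS_cons length differs from alignment width")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise KeyError(f"id {rid!r} not in alignment")

    def member(self, rid: str) -> RnaSequence:
        """The ungapped sequence of one row."""
        gapped = self.row(rid)
        residues = "".join(c for c in gapped if c not in GAP_CHARS)
        return RnaSequence(rid, normalize_residues(residues))


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure of length n."""

    dotbracket: str
    pairs: frozenset = field(default=frozenset())

    def __len__(self) -> int:
        return len(self.dotbracket)

    def partner(self) -> dict[int, int]:
        d = {}
        for p, q in self.pairs:
            d[p], d[q] = q, p
        return d


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, on_unknown: str = "skip") -> list[RnaSequence]:
    """Read a multi-record FASTA file into normalised :class:`RnaSequence`.

    Records containing residues outside {A,C,G,U,T} (any case) are skipped
    with a warning under the default policy, or rejected with an error when
    ``on_unknown="reject"``.
    """
    if on_unknown not in ("skip", "reject"):
        raise ValueError("on_unknown must be 'skip' or 'reject'")
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = normalize_residues(str(rec.seq))
        if set(residues) - _VALID or not residues:
            if on_unknown == "reject":
                raise FormatError(f"record {rec.id!r} contains unknown bases")
            warnings.warn(f"skipping record {rec.id!r}: unknown bases", stacklevel=2)
            continue
        out.append(RnaSequence(rec.id, residues))
    return out


def write_fasta(path, seqs: list[RnaSequence]) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


# ---------------------------------------------------------------------------
# Stockholm

_OPEN = {"(": "(", "<": "(", "[": "(", "{": "("}
_CLOSE = {")": ")", ">": ")", "]": ")", "}": ")"}


def _normalize_ss_line(ss: str) -> str:
    """Map WUSS bracket aliases to (), everything else to '.'.

    Pseudoknot letters (Aa, Bb, ...) are dropped with a warning: the model
    has no notion of pseudoknots.
    """
    out = []
    had_pk = False
    for c in ss:
        if c in _OPEN:
            out.append("(")
        elif c in _CLOSE:
            out.append(")")
        elif c.isalpha():
            had_pk = True
            out.append(".")
        else:
            out.append(".")
    if had_pk:
        warnings.warn("pseudoknot letters in SS_cons dropped", stacklevel=3)
    return "".join(out)


def read_stockholm(path) -> MultipleAlignment:
    """Parse a Stockholm 1.0 alignment; captures ``#=GC SS_cons`` if present."""
    text = Path(path).read_text()
    if not text.lstrip().startswith("# STOCKHOLM"):
        raise FormatError("missing '# STOCKHOLM 1.0' header")
    try:
        aln = AlignIO.read(StringIO(text), "stockholm")
    except ValueError as exc:
        raise FormatError(f"cannot parse Stockholm file: {exc}") from exc
    rows = [(rec.id, str(rec.seq).upper().replace("T", "U")) for rec in aln]
    ss = aln.column_annotations.get("secondary_structure")
    ss_cons = _normalize_ss_line(ss) if ss else None
    return MultipleAlignment(rows=rows, ss_cons=ss_cons)


def write_stockholm(path, msa: MultipleAlignment) -> None:
    """Emit a minimal Stockholm 1.0 file, '-' for gaps, one line per row."""
    width = max((len(rid) for rid, _ in msa.rows), default=0)
    width = max(width, len("#=GC SS_cons"))
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for rid, gapped in msa.rows:
            fh.write(f"{rid:<{width}} {gapped.replace('.', '-')}\n")
        if msa.ss_cons is not None:
            fh.write(f"{'#=GC SS_cons':<{width}} {msa.ss_cons}\n")
        fh.write("//\n")


def extract_pairwise(msa: MultipleAlignment, id_a: str, id_b: str) -> PairwiseAlignment:
    """Project two rows of a reference MSA to a pairwise alignment.

    Columns where both rows are gaps are dropped; the rest become (i, j)
    matches or one-sided gap columns with 1-based ungapped positions.
    """
    row_a, row_b = msa.row(id_a), msa.row(id_b)
    cols: list[tuple[int | None, int | None]] = []
    i = j = 0
    for ca, cb in zip(row_a, row_b):
        ga, gb = ca in GAP_CHARS, cb in GAP_CHARS
        if ga and gb:
            continue
        if not ga:
            i += 1
        if not gb:
            j += 1
        cols.append((None if ga else i, None if gb else j))
    return PairwiseAlignment(cols)


# ---------------------------------------------------------------------------
# Dot-bracket and substructure annotation


def parse_dotbracket(s: str) -> SecondaryStructure:
    """Parse ``(``/``)``/``.`` into a pair set by stack matching."""
    stack: list[int] = []
    pairs = set()
    for pos, c in enumerate(s, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif c != ".":
            raise FormatError(f"invalid character {c!r} at position {pos}")
    if stack:
        raise FormatError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(dotbracket=s, pairs=frozenset(pairs))


def to_dotbracket(pairs, n: int) -> str:
    out = ["."] * n
    for p, q in pairs:
        out[p - 1], out[q - 1] = "(", ")"
    return "".join(out)


def annotate_substructures(ss: SecondaryStructure) -> list[str]:
    """Assign each position one of the six substructure classes.

    Paired positions are stem pairs. An unpaired position is classified by
    the loop of its directly enclosing pair: a loop with no branching
    helices is a hairpin, with one a bulge/internal loop, with two or more
    a multibranch loop. Positions outside all pairs are external, 5' before
    the first paired position and 3' otherwise.
    """
    n = len(ss)
    partner = ss.partner()
    paired_positions = sorted(partner)
    labels = [""] * n

    # innermost enclosing pair for every position (stack sweep)
    enclosing: list[tuple[int, int] | None] = [None] * n
    stack: list[int] = []
    for pos in range(1, n + 1):
        c = ss.dotbracket[pos - 1]
        if c == "(":
            stack.append(pos)
        elif c == ")":
            stack.pop()
        if pos not in partner:
            enclosing[pos - 1] = (stack[-1], partner[stack[-1]]) if stack else None

    # number of helices branching directly inside each pair's loop
    branches: dict[tuple[int, int], int] = {}
    for p, q in partner.items():
        if p > q:
            continue
        count = 0
        pos = p + 1
        while pos < q:
            if pos in partner and partner[pos] > pos:
                count += 1
                pos = partner[pos] + 1
            else:
                pos += 1
        branches[(p, q)] = count

    first_paired = paired_positions[0] if paired_positions else None
    for pos in range(1, n + 1):
        if pos in partner:
            labels[pos - 1] = "stem-pair"
            continue
        enc = enclosing[pos - 1]
        if enc is None:
            if first_paired is None or pos < first_paired:
                labels[pos - 1] = "external-5prime"
            else:
                labels[pos - 1] = "external-3prime"
        else:
            k = branches[enc]
            if k == 0:
                labels[pos - 1] = "hairpin-loop"
            elif k == 1:
                labels[pos - 1] = "bulge-or-internal-loop"
            else:
                labels[pos - 1] = "multibranch-loop"
    return labels
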