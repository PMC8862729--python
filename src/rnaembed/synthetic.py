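"""Synthetic ncRNA families with known structure and reference alignments.

Families are sampled from a random consensus sequence constrained to a
given consensus secondary structure: paired columns always hold
Watson-Crick pairs. Members diverge from the consensus by per-position
substitutions (compensatory at paired columns, so stems stay paired) and
by short insertions/deletions restricted to loop columns, so the
consensus structure remains well defined for every member. Because every
member is generated column-by-column from the consensus, the true
multiple alignment — and hence every true pairwise alignment — is known
exactly. This emulates, at toy scale, curated seed alignments and an
identity-stratified pairwise alignment benchmark.

Sequence identity of a pair is matched-column agreement divided by
matched-column count in the true alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import (
    MultipleAlignment,
    PairwiseAlignment,
    RnaSequence,
    SecondaryStructure,
    annotate_substructures,
    extract_pairwise,
    parse_dotbracket,
)

__all__ = [
    "FamilySpec",
    "SyntheticFamily",
    "BenchmarkPair",
    "generate_family",
    "make_benchmark",
    "random_structure",
    "default_family_specs",
    "pair_identity",
]

WC = {"A": "U", "U": "A", "C": "G", "G": "C"}
WC_PAIRS = ["AU", "UA", "CG", "GC"]
BASES = "ACGU"


@dataclass
class FamilySpec:
    name: str
    consensus_structure: SecondaryStructure
    n_members: int = 6
    substitution_rate: float = 0.18
    indel_rate: float = 0.12
    compensatory: bool = True
    identity_target: tuple[float, float] | None = None
    max_insert: int = 2
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.substitution_rate <= 1 or not 0 <= self.indel_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        if self.n_members < 2:
            raise ValueError("a family needs at least two members")

    @property
    def consensus_len(self) -> int:
        return len(self.consensus_structure)


@dataclass
class SyntheticFamily:
    spec: FamilySpec
    consensus: str
    members: list[RnaSequence]
    msa: MultipleAlignment
    truth_pairs: dict = field(default_factory=dict)

    def truth(self, id_a: str, id_b: str) -> PairwiseAlignment:
        return self.truth_pairs[(id_a, id_b)]


@dataclass
class BenchmarkPair:
    family: str
    seq_a: RnaSequence
    seq_b: RnaSequence
    reference: PairwiseAlignment
    identity: float
    identity_bin: str


# ---------------------------------------------------------------------------
# consensus structures


def random_structure(
    rng: np.random.Generator,
    n_stems: int = 2,
    stem_len: tuple[int, int] = (5, 9),
    loop_len: tuple[int, int] = (5, 10),
    tail_len: tuple[int, int] = (3, 7),
) -> SecondaryStructure:
    """A random pseudoknot-free structure of hairpins joined by linkers."""
    parts = ["." * rng.integers(*tail_len)]
    for s in range(n_stems):
        stem = int(rng.integers(*stem_len))
        loop = int(rng.integers(*loop_len))
        parts.append("(" * stem + "." * loop + ")" * stem)
        parts.append("." * rng.integers(*tail_len))
    return parse_dotbracket("".join(parts))


def _random_consensus(structure: SecondaryStructure, rng: np.random.Generator) -> str:
    seq = [rng.choice(list(BASES)) for _ in range(len(structure))]
    for p, q in structure.pairs:
        a, b = WC_PAIRS[rng.integers(4)]
        seq[p - 1], seq[q - 1] = a, b
    return "".join(seq)


# ---------------------------------------------------------------------------
# member generation

# per-member working form: residue per consensus column (None = deleted)
# plus an inserted string after each consensus column


def _mutate_member(
    consensus: str,
    structure: SecondaryStructure,
    loop_cols: list[int],
    spec: FamilySpec,
    rng: np.random.Generator,
):
    L = len(consensus)
    residues: list[str | None] = list(consensus)
    inserts = [""] * (L + 1)

    # substitutions: paired columns handled per pair, compensatory keeps WC
    done = set()
    for p, q in sorted(structure.pairs):
        done.update((p, q))
        if rng.random() < spec.substitution_rate:
            current = residues[p - 1] + residues[q - 1]
            choices = [pq for pq in WC_PAIRS if pq != current]
            pair = choices[rng.integers(len(choices))]
            if spec.compensatory:
                residues[p - 1], residues[q - 1] = pair[0], pair[1]
            else:
                residues[p - 1] = pair[0]  # partner untouched: may break WC
    for col in range(1, L + 1):
        if col in done:
            continue
        if rng.random() < spec.substitution_rate:
            others = [b for b in BASES if b != residues[col - 1]]
            residues[col - 1] = others[rng.integers(3)]

    # indels only at loop columns
    for col in loop_cols:
        u = rng.random()
        if u < spec.indel_rate / 2:
            residues[col - 1] = None
        elif u < spec.indel_rate:
            k = int(rng.integers(1, spec.max_insert + 1))
            inserts[col] = "".join(rng.choice(list(BASES)) for _ in range(k))
    if all(r is None for r in residues):
        residues[0] = consensus[0]
    return residues, inserts


def _member_identity(ra, rb) -> float:
    """Identity over consensus columns present in both members."""
    both = [(a, b) for a, b in zip(ra, rb) if a is not None and b is not None]
    if not both:
        return 0.0
    return sum(a == b for a, b in both) / len(both)


def generate_family(spec: FamilySpec, rng: np.random.Generator | None = None) -> SyntheticFamily:
    """Sample one family and its true multiple alignment."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    structure = spec.consensus_structure
    consensus = _random_consensus(structure, rng)
    labels = annotate_substructures(structure)
    loop_cols = [c for c in range(1, len(consensus) + 1) if labels[c - 1] != "stem-pair"]

    members = []
    tries = 0
    while len(members) < spec.n_members:
        tries += 1
        if tries > 500 * spec.n_members:
            raise RuntimeError(
                f"family {spec.name!r}: cannot satisfy identity band "
                f"{spec.identity_target} at the configured rates"
            )
        cand = _mutate_member(consensus, structure, loop_cols, spec, rng)
        if spec.identity_target is not None:
            lo, hi = spec.identity_target
            if not all(lo <= _member_identity(cand[0], prev[0]) <= hi for prev in members):
                continue
        members.append(cand)

    # assemble the global MSA: consensus columns + per-member insert blocks
    n_mem = len(members)
    rows = [[] for _ in range(n_mem)]
    ss_cols = []
    L = len(consensus)
    for col in range(0, L + 1):
        if col >= 1:
            for t in range(n_mem):
                r = members[t][0][col - 1]
                rows[t].append(r if r is not None else "-")
            ss_cols.append(structure.dotbracket[col - 1])
        for t in range(n_mem):
            ins = members[t][1][col]
            if not ins:
                continue
            for c in ins:
                for u in range(n_mem):
                    rows[u].append(c if u == t else "-")
                ss_cols.append(".")

    ids = [f"{spec.name}/{t + 1}" for t in range(n_mem)]
    msa = MultipleAlignment(
        rows=[(ids[t], "".join(rows[t])) for t in range(n_mem)],
        ss_cons="".join(ss_cols),
    )
    seqs = [msa.member(i) for i in ids]
    truth = {}
    for a in range(n_mem):
        for b in range(n_mem):
            if a != b:
                truth[(ids[a], ids[b])] = extract_pairwise(msa, ids[a], ids[b])
    return SyntheticFamily(
        spec=spec, consensus=consensus, members=seqs, msa=msa, truth_pairs=truth
    )


# ---------------------------------------------------------------------------
# benchmarks


def pair_identity(aln: PairwiseAlignment, a: RnaSequence, b: RnaSequence) -> float:
    """Matched-column agreement / matched-column count of a true alignment."""
    pairs = aln.matched_pairs()
    if not pairs:
        return 0.0
    agree = sum(a.residues[i - 1] == b.residues[j - 1] for i, j in pairs)
    return agree / len(pairs)


DEFAULT_BINS = ((0.0, 0.4), (0.4, 0.6), (0.6, 0.8), (0.8, 1.0))


def _bin_label(identity: float, bins) -> str:
    for lo, hi in bins:
        if lo <= identity < hi or (hi == 1.0 and identity == 1.0):
            return f"{lo:.1f}-{hi:.1f}"
    return "out-of-range"


def make_benchmark(
    families: list[SyntheticFamily],
    bins=DEFAULT_BINS,
    holdout_families: set[str] | None = None,
) -> list[BenchmarkPair]:
    """All member pairs of the given families, tagged with identity bins.

    When ``holdout_families`` is given only those families are emitted,
    supporting train/test splits with zero family overlap.
    """
    if not families:
        raise ValueError("need at least one family")
    out = []
    for fam in families:
        if holdout_families is not None and fam.spec.name not in holdout_families:
            continue
        members = fam.members
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                ref = fam.truth(members[a].id, members[b].id)
                ident = pair_identity(ref, members[a], members[b])
                out.append(
                    BenchmarkPair(
                        family=fam.spec.name,
                        seq_a=members[a],
                        seq_b=members[b],
                        reference=ref,
                        identity=ident,
                        identity_bin=_bin_label(ident, bins),
                    )
                )
    return out


def default_family_specs(
    n_families: int,
    rng: np.random.Generator,
    n_members: int = 6,
    substitution_rate: float = 0.18,
    indel_rate: float = 0.12,
) -> list[FamilySpec]:
    """Study-condition family specs: 2-3 hairpins, ~40-90 nt consensus."""
    specs = []
    for f in range(n_families):
        n_stems = 2 + int(rng.integers(0, 2))
        structure = random_structure(rng, n_stems=n_stems)
        specs.append(
            FamilySpec(
                name=f"fam{f + 1}",
                consensus_structure=structure,
                n_members=n_members,
                substitution_rate=substitution_rate,
                indel_rate=indel_rate,
                compensatory=True,
            )
        )
    return specs
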