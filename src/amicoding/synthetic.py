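"""Synthetic genomes with the statistical contrast the classifiers exploit.

The coding model draws codons i.i.d. from a biased codon-usage table.
Codon-usage bias makes the three codon positions compositionally distinct,
which induces the period-3 structure of real coding DNA: the lag-k joint
nucleotide distribution is a phase mixture, and at lags that are multiples
of three the two positions share a codon phase, inflating the mutual
information there.  No amino-acid-level structure, start/stop placement or
ORF grammar is modeled — codon abundance bias is deliberately the only
coding signal.

The noncoding model is an order-1 Markov chain with an AT-rich stationary
composition, plus occasional poly-T runs (the antisense trace of poly-A
tails, a strong noncoding indicator).

Default parameters (frozen; see docs/methods.md for rationale):

* codon table: up to two preferred synonymous codons per amino acid — the
  G/C-ending ones, which concentrates the bias on the third codon position
  and maximizes the period-3 signal — with an 8:1 preference ratio;
* noncoding chain: stationary composition A .30, C .17, G .13, T .40 with
  20% same-base persistence; poly-T insertion rate 0.002/base, geometric
  run length with mean 8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import BASES
from .sequence_io import CdsFeature, GenomicInterval, ParentSequences, reverse_complement

__all__ = [
    "STOP_CODONS",
    "SENSE_CODONS",
    "GENETIC_CODE",
    "CodonUsageTable",
    "NoncodingModel",
    "SyntheticGenomeSpec",
    "AnnotatedGenome",
    "generate_coding_parent",
    "generate_noncoding_parent",
    "generate_annotated_genome",
    "gtf_lines",
    "write_genome",
    "SyntheticError",
]

STOP_CODONS = ("TAA", "TAG", "TGA")

# standard genetic code, written out so the table is self-contained
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}

SENSE_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class SyntheticError(ValueError):
    pass


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class CodonUsageTable:
    """Sense-codon sampling weights (stop codons carry zero weight).

    ``bias_strength`` records the preferred:non-preferred weight ratio the
    table was built with (0 or 1 = unbiased); it is metadata, the weights
    are authoritative.
    """

    weights: np.ndarray  # length 61, sums to 1, aligned with SENSE_CODONS
    bias_strength: float = 0.0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(SENSE_CODONS),):
            raise SyntheticError(f"need {len(SENSE_CODONS)} codon weights")
        if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise SyntheticError("codon weights must be nonnegative and sum to 1")
        object.__setattr__(self, "weights", w / w.sum())

    @classmethod
    def uniform(cls) -> "CodonUsageTable":
        n = len(SENSE_CODONS)
        return cls(np.full(n, 1.0 / n), bias_strength=1.0)

    @classmethod
    def biased(cls, bias_strength: float = 8.0) -> "CodonUsageTable":
        """Preferred = up to two G/C-ending codons per amino acid, ratio ``bias_strength``:1."""
        if bias_strength < 0:
            raise SyntheticError("bias_strength must be >= 0")
        by_aa: dict[str, list[str]] = {}
        for c in SENSE_CODONS:
            by_aa.setdefault(GENETIC_CODE[c], []).append(c)
        preferred: set[str] = set()
        for cods in by_aa.values():
            gc_ending = [c for c in sorted(cods) if c[2] in "GC"]
            preferred.update((gc_ending or sorted(cods))[:2])
        w = np.array(
            [bias_strength if c in preferred else 1.0 for c in SENSE_CODONS]
        )
        return cls(w / w.sum(), bias_strength=bias_strength)

    def base_frequencies(self) -> np.ndarray:
        """Implied per-base composition of an i.i.d.-codon sequence."""
        freqs = np.zeros(4)
        for codon, w in zip(SENSE_CODONS, self.weights):
            for b in codon:
                freqs[_BASE_INDEX[b]] += w / 3.0
        return freqs


@dataclass(frozen=True)
class NoncodingModel:
    """Order-1 Markov background with optional poly-T run insertion."""

    transition: np.ndarray  # 4x4 row-stochastic
    initial: np.ndarray  # length 4, the stationary distribution
    polyt_rate: float = 0.002  # insertion probability per base
    polyt_mean_run: float = 8.0  # geometric mean run length

    def __post_init__(self):
        P = np.asarray(self.transition, dtype=float)
        pi = np.asarray(self.initial, dtype=float)
        if P.shape != (4, 4) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise SyntheticError("transition must be 4x4 row-stochastic")
        if pi.shape != (4,) or not np.isclose(pi.sum(), 1.0, atol=1e-9):
            raise SyntheticError("initial must be a length-4 distribution")
        if self.polyt_rate < 0 or self.polyt_mean_run < 1:
            raise SyntheticError("invalid poly-T parameters")
        object.__setattr__(self, "transition", P)
        object.__setattr__(self, "initial", pi)

    @classmethod
    def uniform(cls, polyt_rate: float = 0.0, polyt_mean_run: float = 8.0) -> "NoncodingModel":
        """Memoryless uniform background (the i.i.d. null)."""
        return cls(np.full((4, 4), 0.25), np.full(4, 0.25), polyt_rate, polyt_mean_run)

    @classmethod
    def at_rich(
        cls,
        stationary: tuple[float, float, float, float] = (0.30, 0.17, 0.13, 0.40),
        persistence: float = 0.2,
        polyt_rate: float = 0.002,
        polyt_mean_run: float = 8.0,
    ) -> "NoncodingModel":
        """AT-rich chain ``P = (1 - persistence) * 1·pi + persistence * I``.

        This mixture form keeps ``pi`` exactly stationary while giving
        same-base runs a mild excess over the i.i.d. case.
        """
        pi = np.asarray(stationary, dtype=float)
        pi = pi / pi.sum()
        P = (1 - persistence) * np.tile(pi, (4, 1)) + persistence * np.eye(4)
        return cls(P, pi, polyt_rate, polyt_mean_run)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Layout of one synthetic annotated "species" genome."""

    species_id: str = "synthA"
    codon_table: CodonUsageTable = field(default_factory=lambda: CodonUsageTable.biased())
    noncoding_model: NoncodingModel = field(default_factory=lambda: NoncodingModel.at_rich())
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (300, 1500)  # bp, rounded down to codons
    intergenic_length_range: tuple[int, int] = (200, 800)  # bp
    n_contigs: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_contigs < 1:
            raise SyntheticError("need at least one gene and one contig")
        if self.gene_length_range[0] < 3 or self.intergenic_length_range[0] < 1:
            raise SyntheticError("lengths must be positive (genes >= 3 bp)")


@dataclass(frozen=True)
class AnnotatedGenome:
    """A generated genome plus the ground truth it embeds."""

    contigs: dict[str, str]
    cds_features: list[CdsFeature]
    parents: ParentSequences


# ---------------------------------------------------------------------------
# parent generators


def generate_coding_parent(
    table: CodonUsageTable, length_bp: int, seed=0
) -> str:
    """I.i.d. codon draws from ``table``, truncated to ``length_bp`` bases."""
    if length_bp < 3:
        raise SyntheticError("length_bp must be >= 3")
    rng = _rng(seed)
    n_codons = -(-length_bp // 3)
    idx = rng.choice(len(SENSE_CODONS), size=n_codons, p=table.weights)
    return "".join(SENSE_CODONS[i] for i in idx)[:length_bp]


def _markov_codes(model: NoncodingModel, n: int, rng: np.random.Generator) -> np.ndarray:
    cum = model.transition.cumsum(axis=1)
    cum[:, -1] = 1.0
    u = rng.random(n)
    out = np.empty(n, dtype=np.int8)
    state = int(rng.choice(4, p=model.initial))
    out[0] = state
    for i in range(1, n):
        row = cum[state]
        ui = u[i]
        state = 0 if ui < row[0] else 1 if ui < row[1] else 2 if ui < row[2] else 3
        out[i] = state
    return out


def generate_noncoding_parent(model: NoncodingModel, length_bp: int, seed=0) -> str:
    """Markov-chain sample with poly-T runs spliced in, exactly ``length_bp`` bases."""
    if length_bp < 1:
        raise SyntheticError("length_bp must be >= 1")
    rng = _rng(seed)
    codes = _markov_codes(model, length_bp, rng)
    if model.polyt_rate > 0:
        n_runs = rng.binomial(length_bp, model.polyt_rate)
        if n_runs > 0:
            positions = np.sort(rng.integers(0, length_bp + 1, size=n_runs))
            run_lengths = rng.geometric(1.0 / model.polyt_mean_run, size=n_runs)
            pieces = []
            prev = 0
            t_code = _BASE_INDEX["T"]
            for pos, rl in zip(positions, run_lengths):
                pieces.append(codes[prev:pos])
                pieces.append(np.full(rl, t_code, dtype=np.int8))
                prev = pos
            pieces.append(codes[prev:])
            codes = np.concatenate(pieces)[:length_bp]
    return "".join(BASES[c] for c in codes)


# ---------------------------------------------------------------------------
# annotated genome


def generate_annotated_genome(spec: SyntheticGenomeSpec) -> AnnotatedGenome:
    """Interleave generated genes with noncoding stretches on one or more contigs.

    Genes land on random strands; a minus-strand gene is reverse
    complemented onto the genome, so extraction recovers the original
    coding sequence.  The returned ground-truth parents follow the same
    conventions as :func:`amicoding.sequence_io.build_parent_sequences`
    (per-transcript 5'→3' coding concatenation with deduplication;
    noncoding intervals contribute forward sequence then reverse
    complement, in coordinate order), so round-trip extraction is exact
    whenever the generated gene sequences are distinct — the generator
    deduplicates its own ground truth to keep the invariant exact even on
    collisions.
    """
    rng = np.random.default_rng(spec.seed)
    genes_per_contig = np.full(spec.n_contigs, spec.n_genes // spec.n_contigs)
    genes_per_contig[: spec.n_genes % spec.n_contigs] += 1
    genes_per_contig = genes_per_contig[genes_per_contig > 0]

    contigs: dict[str, str] = {}
    features: list[CdsFeature] = []
    coding_pieces: list[str] = []
    noncoding_pieces: list[str] = []
    gene_no = 0
    glo, ghi = spec.gene_length_range
    ilo, ihi = spec.intergenic_length_range

    for ci, n_genes in enumerate(genes_per_contig):
        name = f"contig{ci + 1}"
        parts: list[str] = []
        pos = 1  # 1-based coordinate of the next base to place
        for gi in range(n_genes):
            inter_len = int(rng.integers(ilo, ihi + 1))
            inter = generate_noncoding_parent(spec.noncoding_model, inter_len, rng)
            parts.append(inter)
            noncoding_pieces.append(inter)
            noncoding_pieces.append(reverse_complement(inter))
            pos += inter_len

            gene_len = (int(rng.integers(glo, ghi + 1)) // 3) * 3
            gene = generate_coding_parent(spec.codon_table, gene_len, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = gene if strand == "+" else reverse_complement(gene)
            parts.append(placed)
            gene_no += 1
            features.append(
                CdsFeature(
                    f"t{gene_no}",
                    GenomicInterval(name, pos, pos + gene_len - 1, strand),
                )
            )
            coding_pieces.append(gene)
            pos += gene_len
        tail_len = int(rng.integers(ilo, ihi + 1))
        tail = generate_noncoding_parent(spec.noncoding_model, tail_len, rng)
        parts.append(tail)
        noncoding_pieces.append(tail)
        noncoding_pieces.append(reverse_complement(tail))
        contigs[name] = "".join(parts)

    seen: set[str] = set()
    deduped = []
    for p in coding_pieces:
        if p not in seen:
            seen.add(p)
            deduped.append(p)
    parents = ParentSequences(
        spec.species_id, "".join(deduped), "".join(noncoding_pieces)
    )
    return AnnotatedGenome(contigs, features, parents)


def gtf_lines(genome: AnnotatedGenome, source: str = "amicoding") -> list[str]:
    """Render the genome's CDS features as 9-column GTF rows."""
    lines = []
    for f in genome.cds_features:
        iv = f.interval
        attrs = f'gene_id "{f.transcript_id}"; transcript_id "{f.transcript_id}";'
        lines.append(
            f"{iv.seqid}\t{source}\tCDS\t{iv.start}\t{iv.end}\t.\t{iv.strand}\t0\t{attrs}"
        )
    return lines


def write_genome(genome: AnnotatedGenome, fasta_path, gtf_path) -> None:
    from .sequence_io import write_fasta

    write_fasta(fasta_path, genome.contigs)
    with open(gtf_path, "w") as fh:
        for line in gtf_lines(genome):
            fh.write(line + "\n")
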