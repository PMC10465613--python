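"""Seeded synthetic genome with transposable-element families and gene loci.

Builds a desk-scale stand-in for a nematode genome: a few chromosomes of
random sequence into which TE copies (with realistic family structure:
shared consensus, small per-copy divergence, random orientation) and gene
loci are planted without overlap.  Copy numbers of the default families
mirror the haploid counts of the *C. elegans* DNA transposons they emulate
(Tc1: 31 copies, Tc3: 22 copies) with a scaled-down stand-in for the
high-copy Cele14 family.

Every family consensus carries one DpnI assay site in a fixed context
(``GATCC``) and one PvuII site (``CAGCTG``); these motifs are protected from
per-copy divergence because the downstream restriction-ligation assay
depends on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import GFFParseError, SizingError

log = logging.getLogger(__name__)

GFF_SOURCE = "temeth-age"
FEATURE_KINDS = ("te_copy", "gene", "control_gene")

#: DpnI recognition site in the context that leaves a ``TCC`` genomic head
#: after the blunt GA^TC cut (the context the packaged junction primers use).
DPNI_ASSAY_MOTIF = "GATCC"
PVUII_MOTIF = "CAGCTG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

DEFAULT_SEED = 1729


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySpec:
    """A TE family: consensus sequence, haploid copy number, activity flag.

    ``consensus`` may be ``None`` for specs reconstructed from a repeat-hit
    table (where only per-copy coordinates survive); ``length`` then carries
    the element length.
    """

    family_id: str
    consensus: str | None
    copy_count: int
    active: bool = True
    length: int | None = None

    def __post_init__(self):
        if self.copy_count < 1:
            raise ValueError(f"{self.family_id}: copy_count must be >= 1")
        if self.consensus is not None:
            if len(self.consensus) < 200:
                raise ValueError(f"{self.family_id}: consensus shorter than 200 bp")
            if "GATC" not in self.consensus:
                raise ValueError(f"{self.family_id}: consensus lacks a GATC site")
            object.__setattr__(self, "length", len(self.consensus))
        elif self.length is None:
            raise ValueError(f"{self.family_id}: need consensus or length")

    @property
    def consensus_length(self) -> int:
        return self.length  # type: ignore[return-value]


@dataclass(frozen=True)
class Feature:
    """A planted genomic feature, 0-based half-open coordinates."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str
    family_id: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.feature_id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.feature_id}: strand must be + or -")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"{self.feature_id}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class WorldConfig:
    chrom_lengths: list[int]
    te_families: list[FamilySpec]
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (2000, 6000)
    control_gene_length: int = 4000
    per_copy_divergence: float = 0.02
    seed: int = DEFAULT_SEED


@dataclass
class GenomeBuild:
    sequences: dict[str, str]
    features: list[Feature]
    family_index: dict[str, FamilySpec]

    def feature_sequence(self, feature: Feature) -> str:
        """Plus-strand genomic sequence of a feature."""
        return self.sequences[feature.chrom][feature.start:feature.end]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


def _plant(arr: np.ndarray, motif: str, pos: int) -> None:
    arr[pos:pos + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)


def make_consensus(rng: np.random.Generator, length: int) -> str:
    """Random consensus with one DpnI assay site and one PvuII site planted."""
    arr = _random_dna(rng, length)
    _plant(arr, DPNI_ASSAY_MOTIF, length // 3)
    _plant(arr, PVUII_MOTIF, (2 * length) // 3)
    return arr.tobytes().decode()


def default_config(seed: int = DEFAULT_SEED) -> WorldConfig:
    """The packaged default world: 2 x 500 kb chromosomes, three TE families
    with the copy-number hierarchy of the nematode families they stand in for
    (31 Tc1-like, 22 Tc3-like, 60 Cele14-like), and 20 genes including one
    4 kb control gene (a cep-1/p53-like non-TE locus)."""
    rng = np.random.default_rng(seed)
    families = [
        FamilySpec("Tc1-like", make_consensus(rng, 1610), 31, active=True),
        FamilySpec("Tc3-like", make_consensus(rng, 2335), 22, active=True),
        FamilySpec("Cele14-like", make_consensus(rng, 1000), 60, active=True),
    ]
    return WorldConfig(
        chrom_lengths=[500_000, 500_000],
        te_families=families,
        seed=seed,
    )


def _protected_mask(consensus: str) -> np.ndarray:
    """Positions inside any GATC or CAGCTG occurrence; never mutated."""
    mask = np.zeros(len(consensus), dtype=bool)
    for motif in ("GATC", PVUII_MOTIF):
        start = consensus.find(motif)
        while start != -1:
            mask[start:start + len(motif)] = True
            start = consensus.find(motif, start + 1)
    return mask


def _mutate_copy(rng: np.random.Generator, consensus: str, rate: float,
                 protected: np.ndarray) -> np.ndarray:
    arr = np.frombuffer(consensus.encode(), dtype=np.uint8).copy()
    hit = (rng.random(arr.size) < rate) & ~protected
    idx = np.nonzero(hit)[0]
    if idx.size:
        # substitute with a uniformly random *different* base
        shift = rng.integers(1, 4, size=idx.size)
        base_ix = np.searchsorted(_BASES, arr[idx])
        arr[idx] = _BASES[(base_ix + shift) % 4]
    return arr


def build_genome(config: WorldConfig) -> GenomeBuild:
    """Plant TE copies and genes into random chromosomes, deterministically.

    Raises :class:`SizingError` if the planted features cannot fit.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{_roman(i + 1)}" for i in range(len(config.chrom_lengths))]

    # enumerate features to plant: (id, kind, family_id, length)
    plan: list[tuple[str, str, str | None, int]] = []
    for fam in config.te_families:
        for i in range(fam.copy_count):
            plan.append((f"{fam.family_id}_copy{i + 1:03d}", "te_copy",
                         fam.family_id, fam.consensus_length))
    lo, hi = config.gene_length_range
    n_plain = max(config.n_genes - 1, 0)
    for i in range(n_plain):
        plan.append((f"gene_{i + 1:03d}", "gene", None, int(rng.integers(lo, hi + 1))))
    if config.n_genes >= 1:
        plan.append(("control_gene_1", "control_gene", None, config.control_gene_length))

    total_len = sum(length for *_, length in plan)
    genome_len = sum(config.chrom_lengths)
    if total_len >= genome_len:
        raise SizingError(
            f"planted features span {total_len} bp but the genome is only "
            f"{genome_len} bp ({total_len - genome_len} bp overflow)")

    # deal features to chromosomes: shuffle, then greedy into most-free chrom
    order = rng.permutation(len(plan))
    free = list(config.chrom_lengths)
    per_chrom: list[list[int]] = [[] for _ in chrom_names]
    for j in order:
        length = plan[j][3]
        c = int(np.argmax(free))
        if free[c] <= length:
            raise SizingError(
                f"feature {plan[j][0]} ({length} bp) does not fit: largest "
                f"remaining free space is {free[c]} bp")
        per_chrom[c].append(j)
        free[c] -= length

    protected = {f.family_id: _protected_mask(f.consensus) for f in config.te_families}
    fam_by_id = {f.family_id: f for f in config.te_families}

    sequences: dict[str, str] = {}
    features: list[Feature] = []
    for c, chrom in enumerate(chrom_names):
        L = config.chrom_lengths[c]
        arr = _random_dna(rng, L)
        members = per_chrom[c]
        lengths = [plan[j][3] for j in members]
        spare = L - sum(lengths)
        # stars-and-bars gaps: uniform cut points over the spare space
        cuts = np.sort(rng.integers(0, spare + 1, size=len(members))) if members else np.array([], dtype=int)
        pos = 0
        prev_cut = 0
        for j, cut in zip(members, cuts):
            fid, kind, fam_id, length = plan[j]
            pos += int(cut - prev_cut)
            prev_cut = cut
            strand = "+" if rng.random() < 0.5 else "-"
            if kind == "te_copy":
                fam = fam_by_id[fam_id]
                copy = _mutate_copy(rng, fam.consensus, config.per_copy_divergence,
                                    protected[fam_id])
                if strand == "-":
                    copy = np.frombuffer(
                        reverse_complement(copy.tobytes().decode()).encode(),
                        dtype=np.uint8).copy()
                arr[pos:pos + length] = copy
            elif kind == "control_gene":
                gene = _random_dna(rng, length)
                _plant(gene, DPNI_ASSAY_MOTIF, length // 3)
                _plant(gene, PVUII_MOTIF, (2 * length) // 3)
                arr[pos:pos + length] = gene
            # plain genes keep the freshly drawn background sequence
            features.append(Feature(fid, chrom, pos, pos + length, strand, kind, fam_id))
            pos += length
        sequences[chrom] = arr.tobytes().decode()

    features.sort(key=lambda f: (f.chrom, f.start))
    return GenomeBuild(sequences=sequences, features=features, family_index=fam_by_id)


def _roman(n: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    return numerals[n - 1] if n <= len(numerals) else str(n)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_world(build: GenomeBuild, outdir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, annotation GFF3 (1-based inclusive) and a
    repeat-hit TSV (one row per TE copy, Dfam-hit-table style)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fasta",
        "gff": outdir / "annotations.gff3",
        "repeats": outdir / "repeats.tsv",
    }

    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in build.sequences.items()]
    SeqIO.write(records, paths["fasta"], "fasta")

    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, seq in build.sequences.items():
            fh.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
        for f in build.features:
            attrs = f"ID={f.feature_id}"
            if f.family_id is not None:
                attrs += f";family_id={f.family_id}"
            fh.write(f"{f.chrom}\t{GFF_SOURCE}\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t"
                     f"{f.strand}\t.\t{attrs}\n")

    rows = []
    for f in build.features:
        if f.kind != "te_copy":
            continue
        fam = build.family_index[f.family_id]
        ident = 100.0
        if fam.consensus is not None:
            copy = build.feature_sequence(f)
            if f.strand == "-":
                copy = reverse_complement(copy)
            mism = sum(a != b for a, b in zip(copy, fam.consensus))
            ident = 100.0 * (1 - mism / fam.consensus_length)
        rows.append((f.family_id, f.chrom, f.start, f.end, f.strand, round(ident, 2)))
    pd.DataFrame(rows, columns=["family_id", "chrom", "start", "end", "strand",
                                "percent_identity"]).to_csv(
        paths["repeats"], sep="\t", index=False)
    return paths


def read_annotations(gff_path: str | Path) -> list[Feature]:
    """Parse the world GFF3 back into 0-based half-open Features.

    Unknown feature types are skipped with a warning; malformed lines raise
    :class:`GFFParseError` with the line number.
    """
    features: list[Feature] = []
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFFParseError(f"expected 9 tab-separated columns, got {len(cols)}",
                                    lineno)
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype not in FEATURE_KINDS:
                log.warning("skipping unknown feature type %r at line %d", ftype, lineno)
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GFFParseError(f"non-integer coordinates: {exc}", lineno) from None
            attr_map = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            fid = attr_map.get("ID", f"feature_{lineno}")
            try:
                features.append(Feature(fid, chrom, start1 - 1, end1, strand, ftype,
                                        attr_map.get("family_id")))
            except ValueError as exc:
                raise GFFParseError(str(exc), lineno) from None
    return features


def read_world(outdir: str | Path) -> GenomeBuild:
    """Reload a written world.  Family consensi are not stored on disk; the
    reconstructed FamilySpecs carry the element length (the copies' span)
    and the copy count observed in the repeat table."""
    outdir = Path(outdir)
    sequences = {rec.id: str(rec.seq)
                 for rec in SeqIO.parse(outdir / "genome.fasta", "fasta")}
    features = read_annotations(outdir / "annotations.gff3")
    repeats = pd.read_csv(outdir / "repeats.tsv", sep="\t")
    family_index: dict[str, FamilySpec] = {}
    for fam_id, grp in repeats.groupby("family_id"):
        lengths = (grp["end"] - grp["start"])
        family_index[str(fam_id)] = FamilySpec(
            str(fam_id), None, len(grp), length=int(lengths.mode().iloc[0]))
    return GenomeBuild(sequences=sequences, features=features, family_index=family_index)


def count_family_copies(features: list[Feature], family_id: str) -> int:
    """Number of te_copy features annotated with the given family."""
    return sum(1 for f in features if f.kind == "te_copy" and f.family_id == family_id)


def write_family_library(build: GenomeBuild, path: str | Path,
                         reference_feature_id: str | None = None) -> Path:
    """Consensus library FASTA (Repbase-style, one entry per family), plus an
    optional reference-gene entry taken from the genome."""
    path = Path(path)
    records = []
    for fam in build.family_index.values():
        if fam.consensus is None:
            raise ValueError(f"{fam.family_id}: no consensus sequence available")
        records.append(SeqRecord(Seq(fam.consensus), id=fam.family_id,
                                 description=f"copy_count={fam.copy_count}"))
    if reference_feature_id is not None:
        feat = next(f for f in build.features if f.feature_id == reference_feature_id)
        records.append(SeqRecord(Seq(build.feature_sequence(feat)),
                                 id=reference_feature_id, description="reference_gene"))
    SeqIO.write(records, path, "fasta")
    return path
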