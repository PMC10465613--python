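"""Age- and genotype-dependent 6mA methylome simulation.

The generator's ground truth is a per-site methylation probability p(t) per
locus class:

* ``te_active`` loci (TE copies) gain 6mA linearly with adult age:
  p(t) = p1 * (1 + k * (t - 1)).  With the default p1 = 0.03 and k = 0.45
  the day-11 level is 5.5x the day-1 level, the midpoint of the 5-6-fold
  increase the restriction-ligation assay is calibrated to recover.
* ``gene_control`` loci (genes, including the p53-like control gene) start
  twice as methylated as TEs at day 1 (p1g = 0.06) and demethylate
  exponentially, p(t) = p1g * exp(-lambda * (t - 1)), with lambda chosen so
  that the TE/gene ratio is exactly 4 at day 5.

Genotypes modify the TE trajectory: ``daf-2`` (long-lived insulin-receptor
mutant) accumulates 6mA at half the wild-type rate; ``nmad-1``
(demethylase-null) sits constitutively at the high plateau; ``damt-1``
(methyltransferase-null) shows only a weak residual level at day 1 and is
near zero from day 5 on.

Excision of a TE copy is modeled as a hazard proportional to the current
methylation probability, giving the cumulative excised fraction
e(t) = 1 - exp(-beta * sum_{u=1..t} p(u)).

Per-molecule states are Bernoulli samples of these probabilities; SMRT-style
per-site modification calls are emitted for every adenine (both strands)
with the probability of the covering feature's trajectory, or a small
background probability elsewhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GFFParseError
from .synthgenome import Feature, GenomeBuild

log = logging.getLogger(__name__)

GENOTYPES = ("wildtype", "daf-2", "nmad-1", "damt-1")
LOCUS_CLASSES = ("te_active", "gene_control")

#: decay rate of the gene-locus trajectory; exactly -ln(0.35)/4 (~0.2625/day)
#: so that p_te(5) / p_gene(5) = 4 under the defaults.
GENE_DECAY_LAMBDA = -math.log(0.35) / 4.0

DEFAULT_BACKGROUND_P = 0.001
DEFAULT_BETA = 0.005
MODCALL_COVERAGE = 50  # placeholder coverage; call scores scale with frac


@dataclass(frozen=True)
class MethylationTrajectory:
    """Parameters of the age -> per-site 6mA probability function."""

    locus_class: str
    p1: float = 0.03                 # baseline per-site probability at day 1
    growth_k: float = 0.45           # per-day linear growth (te_active)
    decay_lambda: float = GENE_DECAY_LAMBDA  # per-day decay (gene_control)
    p_high_nmad1: float = 0.165      # demethylase-null plateau
    p_damt1_early: float = 0.01      # methyltransferase-null, day < 5
    p_damt1_late: float = 0.001      # methyltransferase-null, day >= 5
    stress_multiplier: float = 1.0   # heat stress scales p(t); >= 1

    def __post_init__(self):
        if self.locus_class not in LOCUS_CLASSES:
            raise ConfigurationError(f"unknown locus class {self.locus_class!r}")

    @classmethod
    def te_active(cls, **kw) -> "MethylationTrajectory":
        return cls(locus_class="te_active", **kw)

    @classmethod
    def gene_control(cls, **kw) -> "MethylationTrajectory":
        kw.setdefault("p1", 0.06)
        return cls(locus_class="gene_control", **kw)

    def stressed(self, multiplier: float = 2.0) -> "MethylationTrajectory":
        return replace(self, stress_multiplier=multiplier)


def default_trajectories() -> dict[str, MethylationTrajectory]:
    return {
        "te_active": MethylationTrajectory.te_active(),
        "gene_control": MethylationTrajectory.gene_control(),
    }


def site_fraction(traj: MethylationTrajectory, age_days: float,
                  genotype: str = "wildtype") -> float:
    """Per-site 6mA probability at the given adult age, clipped to [0, 1]."""
    if age_days < 1:
        raise ValueError("age_days must be >= 1 (adult days)")
    if genotype not in GENOTYPES:
        raise ConfigurationError(f"unknown genotype {genotype!r}")
    if traj.locus_class == "gene_control":
        # gene loci demethylate with age irrespective of the TE-pathway genotype
        p = traj.p1 * math.exp(-traj.decay_lambda * (age_days - 1))
    elif genotype == "wildtype":
        p = traj.p1 * (1 + traj.growth_k * (age_days - 1))
    elif genotype == "daf-2":
        p = traj.p1 * (1 + 0.5 * traj.growth_k * (age_days - 1))
    elif genotype == "nmad-1":
        p = traj.p_high_nmad1
    else:  # damt-1
        p = traj.p_damt1_early if age_days < 5 else traj.p_damt1_late
    return min(max(p * traj.stress_multiplier, 0.0), 1.0)


def excision_fraction(traj: MethylationTrajectory, age_days: int,
                      genotype: str = "wildtype", beta: float = DEFAULT_BETA) -> float:
    """Cumulative fraction of molecules with the element excised by day t.

    The excision hazard is proportional to the current methylation
    probability, so e(t) = 1 - exp(-beta * sum_{u=1..t} p(u)).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    cumulative = sum(site_fraction(traj, u, genotype)
                     for u in range(1, int(age_days) + 1))
    return 1.0 - math.exp(-beta * cumulative)


# ---------------------------------------------------------------------------
# per-molecule sampling
# ---------------------------------------------------------------------------

@dataclass
class MoleculePool:
    """Sampled per-molecule states at one locus (one assayed site)."""

    locus: str
    n_molecules: int
    methylated: np.ndarray  # bool per molecule
    excised: np.ndarray     # bool per molecule; excised => not methylated
    age_days: float
    genotype: str

    def __post_init__(self):
        assert self.methylated.shape == (self.n_molecules,)
        assert self.excised.shape == (self.n_molecules,)

    @property
    def methylated_fraction(self) -> float:
        return float(self.methylated.mean()) if self.n_molecules else 0.0

    @property
    def excised_fraction(self) -> float:
        return float(self.excised.mean()) if self.n_molecules else 0.0


def sample_molecules(p: float, n_molecules: int, seed: int, *,
                     locus: str = "locus", age_days: float = 1.0,
                     genotype: str = "wildtype") -> MoleculePool:
    """Bernoulli(p) methylation state per molecule; no excision."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be a probability")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    meth = rng.random(n_molecules) < p
    return MoleculePool(locus, n_molecules, meth,
                        np.zeros(n_molecules, dtype=bool), age_days, genotype)


def sample_pool(traj: MethylationTrajectory, age_days: float, genotype: str,
                n_molecules: int, seed: int, *, beta: float = DEFAULT_BETA,
                locus: str = "locus") -> MoleculePool:
    """Joint methylation/excision sample.  Excision is drawn first; an
    excised molecule has no element left to methylate at the assayed site."""
    p = site_fraction(traj, age_days, genotype)
    e = excision_fraction(traj, int(age_days), genotype, beta)
    rng = np.random.default_rng(seed)
    excised = rng.random(n_molecules) < e
    meth = (rng.random(n_molecules) < p) & ~excised
    return MoleculePool(locus, n_molecules, meth, excised, age_days, genotype)


# ---------------------------------------------------------------------------
# modification calls (SMRT/ipdSummary-style)
# ---------------------------------------------------------------------------

_KIND_TO_CLASS = {"te_copy": "te_active", "gene": "gene_control",
                  "control_gene": "gene_control"}


@dataclass
class ModCallSet:
    """Per-site m6A call records as a DataFrame
    (chrom, pos [0-based], strand, score, coverage, frac)."""

    df: pd.DataFrame

    COLUMNS = ("chrom", "pos", "strand", "score", "coverage", "frac")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def empty(cls) -> "ModCallSet":
        return cls(pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            cls.COLUMNS, ("object", "int64", "object", "int64", "int64", "float64"))}))

    def sorted(self) -> pd.DataFrame:
        return (self.df.sort_values(["chrom", "pos", "strand"])
                .reset_index(drop=True))


def emit_modcalls(build: GenomeBuild, trajectories: dict[str, MethylationTrajectory],
                  age_days: float, genotype: str, seed: int,
                  p_background: float = DEFAULT_BACKGROUND_P) -> ModCallSet:
    """Emit one m6A call per adenine (either strand) with the probability of
    the covering feature's trajectory; adenines outside features call at the
    background rate."""
    for f in build.features:
        if _KIND_TO_CLASS[f.kind] not in trajectories:
            raise ConfigurationError(
                f"no trajectory for locus class {_KIND_TO_CLASS[f.kind]!r} "
                f"(feature {f.feature_id})")
    class_p = {cls: site_fraction(traj, age_days, genotype)
               for cls, traj in trajectories.items()}

    rng = np.random.default_rng(seed)
    chunks = []
    for chrom, seq in build.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        p = np.full(arr.size, p_background)
        for f in build.features:
            if f.chrom == chrom:
                p[f.start:f.end] = class_p[_KIND_TO_CLASS[f.kind]]
        for strand, base in (("+", ord("A")), ("-", ord("T"))):
            pos = np.nonzero(arr == base)[0]
            called = pos[rng.random(pos.size) < p[pos]]
            if called.size == 0:
                continue
            frac = p[called]
            chunks.append(pd.DataFrame({
                "chrom": chrom, "pos": called, "strand": strand,
                "score": (20 + np.rint(frac * 200)).astype(int),
                "coverage": MODCALL_COVERAGE, "frac": frac,
            }))
    if not chunks:
        return ModCallSet.empty()
    return ModCallSet(pd.concat(chunks, ignore_index=True))


def write_modcalls(calls: ModCallSet, path) -> None:
    """ipdSummary-like GFF3 dialect: type ``m6A``, 1-based single-base
    interval, integer score, ``coverage=<int>;frac=<float>`` attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("##source temeth modification calls\n")
        for row in calls.sorted().itertuples(index=False):
            fh.write(f"{row.chrom}\tkinModCall\tm6A\t{row.pos + 1}\t{row.pos + 1}\t"
                     f"{row.score}\t{row.strand}\t.\t"
                     f"coverage={row.coverage};frac={row.frac:.6f}\n")


def read_modcalls(path) -> ModCallSet:
    """Parse the modification-call dialect back.  Non-m6A records are skipped
    with a warning; malformed lines raise :class:`GFFParseError`."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFFParseError(f"expected 9 columns, got {len(cols)}", lineno)
            chrom, _src, mtype, start_s, end_s, score_s, strand, _phase, attrs = cols
            if mtype != "m6A":
                log.warning("skipping non-m6A record type %r at line %d", mtype, lineno)
                continue
            try:
                start1, end1, score = int(start_s), int(end_s), int(score_s)
            except ValueError as exc:
                raise GFFParseError(f"bad numeric field: {exc}", lineno) from None
            if start1 != end1:
                raise GFFParseError("modification call must span a single base", lineno)
            attr_map = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            try:
                coverage = int(attr_map["coverage"])
                frac = float(attr_map["frac"])
            except (KeyError, ValueError) as exc:
                raise GFFParseError(f"bad attributes {attrs!r}: {exc}", lineno) from None
            rows.append((chrom, start1 - 1, strand, score, coverage, frac))
    if not rows:
        return ModCallSet.empty()
    return ModCallSet(pd.DataFrame(rows, columns=list(ModCallSet.COLUMNS)))
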