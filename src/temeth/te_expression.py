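"""TE-family transcript simulation and reference-normalized quantification.

Family expression is coupled to the methylation trajectory: the expected
transcript output is lambda = (b + gamma * p(t; genotype)) scaled by any
RNAi knockdown residual factors and a stress multiplier, so expression of
active families rises with age in the wild type, is elevated in the
demethylase mutant and depressed under methyltransferase knockdown.

Quantification mirrors a consensus-library read-assignment workflow: reads
are error-free substrings drawn from family consensi (plus a constant-level
reference gene, the cdc-42 stand-in), assigned back by exact substring
match against the library, and reported relative to the reference-gene
count.  Group comparisons use two-sided Student's t or exact Mann-Whitney U
tests with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, UndefinedRatioError
from .methylome_sim import MethylationTrajectory, site_fraction
from .synthgenome import GenomeBuild, reverse_complement

DEFAULT_BASELINE = 0.2
DEFAULT_COUPLING = 10.0
DEFAULT_KNOCKDOWN_RESIDUAL = 0.5  # RNAi lowers transcripts by about half
REFERENCE_LEVEL = 1.0


@dataclass
class ExpressionModel:
    """Per-family expression parameters and intervention residuals."""

    baselines: dict[str, float]
    coupling: dict[str, float]
    knockdown: dict[str, float]          # intervention name -> residual in (0, 1]
    onset_day: dict[str, int] = field(default_factory=dict)  # delayed activity
    stress_multiplier: float = 1.0
    trajectory: MethylationTrajectory = field(
        default_factory=MethylationTrajectory.te_active)

    @classmethod
    def default(cls, family_ids: list[str]) -> "ExpressionModel":
        return cls(
            baselines={f: DEFAULT_BASELINE for f in family_ids},
            coupling={f: DEFAULT_COUPLING for f in family_ids},
            knockdown={f"{f}_rnai": DEFAULT_KNOCKDOWN_RESIDUAL for f in family_ids},
        )


def expression_level(model: ExpressionModel, family_id: str, age_days: float,
                     genotype: str = "wildtype",
                     interventions: tuple[str, ...] = ()) -> float:
    """Expected transcript level of one family relative to the model scale."""
    if family_id not in model.baselines:
        raise ConfigurationError(f"family {family_id!r} not in expression model")
    onset = model.onset_day.get(family_id, 1)
    effective_age = max(1.0, age_days - onset + 1)
    p = site_fraction(model.trajectory, effective_age, genotype)
    lam = model.baselines[family_id] + model.coupling[family_id] * p
    for iv in interventions:
        if iv not in model.knockdown:
            raise ConfigurationError(f"unknown intervention {iv!r}")
        lam *= model.knockdown[iv]
    return lam * model.stress_multiplier


# ---------------------------------------------------------------------------
# read simulation and assignment
# ---------------------------------------------------------------------------

def expression_library(build: GenomeBuild, reference_gene: str) -> dict[str, str]:
    """Consensus library: one entry per family plus the reference gene."""
    lib = {fam.family_id: fam.consensus for fam in build.family_index.values()
           if fam.consensus is not None}
    feat = next((f for f in build.features if f.feature_id == reference_gene), None)
    if feat is None:
        raise ConfigurationError(f"reference gene {reference_gene!r} not found")
    lib[reference_gene] = build.feature_sequence(feat)
    return lib


def simulate_reads(levels: dict[str, float], library: dict[str, str],
                   reference_gene: str, read_len: int, n_reads: int,
                   seed: int, reference_level: float = REFERENCE_LEVEL
                   ) -> pd.DataFrame:
    """Error-free reads with family proportions given by ``levels`` and a
    fixed reference-gene level; uniform start positions.  Returns a DataFrame
    (read, source) where source is the generating entry (ground truth)."""
    weights = dict(levels)
    weights[reference_gene] = reference_level
    for name, seq in library.items():
        if name in weights and read_len > len(seq):
            raise ValueError(f"read_len {read_len} exceeds library entry {name!r}")
    names = sorted(weights)
    w = np.array([weights[n] for n in names], dtype=float)
    if n_reads == 0 or w.sum() == 0:
        return pd.DataFrame({"read": pd.Series(dtype="object"),
                             "source": pd.Series(dtype="object")})
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, w / w.sum())
    reads, sources = [], []
    for name, cnt in zip(names, counts):
        if cnt == 0:
            continue
        seq = library[name]
        starts = rng.integers(0, len(seq) - read_len + 1, size=cnt)
        reads.extend(seq[s:s + read_len] for s in starts)
        sources.extend([name] * cnt)
    return pd.DataFrame({"read": reads, "source": sources})


@dataclass(frozen=True)
class AssignmentCounts:
    counts: dict[str, int]
    ambiguous: int
    unassigned: int

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.ambiguous + self.unassigned


def assign_reads(reads, library: dict[str, str]) -> AssignmentCounts:
    """Assign each read to the unique library entry containing it as an
    exact substring (either strand); multi-hit reads are ambiguous, no-hit
    reads unassigned.  Counts are conserved."""
    if not library:
        raise ValueError("empty library")
    entries = [(name, seq, reverse_complement(seq)) for name, seq in library.items()]
    counts = {name: 0 for name in library}
    ambiguous = unassigned = 0
    for read in reads:
        hits = [name for name, fwd, rev in entries if read in fwd or read in rev]
        if len(hits) == 1:
            counts[hits[0]] += 1
        elif hits:
            ambiguous += 1
        else:
            unassigned += 1
    return AssignmentCounts(counts, ambiguous, unassigned)


def relative_expression(counts: AssignmentCounts | dict[str, int],
                        reference_gene: str) -> pd.DataFrame:
    """Family counts normalized to the reference-gene count.  Columns:
    family_id, raw_count, reference_count, relative_level."""
    if isinstance(counts, AssignmentCounts):
        counts = counts.counts
    ref = counts.get(reference_gene, 0)
    if ref <= 0:
        raise UndefinedRatioError(f"reference gene {reference_gene!r} has zero count")
    rows = [(name, cnt, ref, cnt / ref)
            for name, cnt in counts.items() if name != reference_gene]
    return pd.DataFrame(rows, columns=["family_id", "raw_count",
                                       "reference_count", "relative_level"])


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def group_compare(group_a: dict[str, np.ndarray], group_b: dict[str, np.ndarray],
                  test: str = "student_t", m: int | None = None) -> pd.DataFrame:
    """Per-family two-sided test between replicate groups with Bonferroni
    correction over ``m`` comparisons (defaults to the number of families).
    Columns: family_id, statistic, p_raw, p_adj."""
    if test not in ("student_t", "mann_whitney"):
        raise ConfigurationError(f"unknown test {test!r}")
    families = sorted(set(group_a) & set(group_b))
    if not families:
        raise ValueError("no shared families between groups")
    m = m if m is not None else len(families)
    rows = []
    for fam in families:
        a = np.asarray(group_a[fam], dtype=float)
        b = np.asarray(group_b[fam], dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"{fam}: need >= 2 replicates per group")
        if test == "student_t":
            if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
                stat, p = 0.0, 1.0  # degenerate: identical constant groups
            else:
                stat, p = stats.ttest_ind(a, b, equal_var=True)
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
            stat, p = res.statistic, res.pvalue
        rows.append((fam, float(stat), float(p), min(1.0, m * float(p))))
    return pd.DataFrame(rows, columns=["family_id", "statistic", "p_raw", "p_adj"])
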