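"""Methylation-sensitive restriction--ligation PCR assay and excision PCR.

The assay quantifies how often a given adenine in a GATC site is
N6-methylated across the individual genomes in a sample.  DpnI cuts GATC
only when the adenine is methylated (blunt, GA^TC); a double-stranded linker
is ligated to the cut ends, and a *junction* forward primer -- the 3' end of
the linker's primer arm fused to the first genomic bases past the cut --
amplifies only molecules that were cut, i.e. methylated.  PvuII (CAG^CTG)
cuts regardless of methylation and provides the loading control; the
readout is target signal normalized to control signal, which in the
non-saturating regime equals the methylated fraction of the pool.

The excision assay uses the same junction-primer idea on a different event:
a forward primer spanning the two flanks of a TE copy amplifies only
molecules in which the element was excised and the flanks juxtaposed.

PCR is modeled as deterministic geometric amplification with a per-cycle
efficiency and a saturation cap; all reported quantities are ratios, so the
amplification factor cancels whenever the regime is linear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import SiteError, SpecificityError, UndefinedRatioError
from .methylome_sim import MoleculePool
from .synthgenome import Feature, GenomeBuild, reverse_complement

# ---------------------------------------------------------------------------
# enzymes and linker
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Enzyme:
    name: str
    recognition: str
    cut_offset: int          # bases from recognition start; blunt cut
    requires_m6a: bool

    def __post_init__(self):
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise ValueError("cut_offset outside recognition site")


DPNI = Enzyme("DpnI", "GATC", 2, requires_m6a=True)
PVUII = Enzyme("PvuII", "CAGCTG", 3, requires_m6a=False)

#: The two strands of the ligated linker.  arm_b is the primer arm: its 3'
#: suffix forms the 5' half of every junction forward primer.
LINKER_ARM_A = "TAGATCTGACCTAACGGTAAGAGAGTTTCATAATATTTTTTTTTTTTTTTTAT"
LINKER_ARM_B = "TATGAAACTCTCTTACCGTTAGGTCAGATCTA"


@dataclass(frozen=True)
class Linker:
    arm_a: str = LINKER_ARM_A
    arm_b: str = LINKER_ARM_B


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def find_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """0-based start positions of all (possibly overlapping) recognition
    sites, ascending."""
    if any(c not in "ACGT" for c in seq):
        raise ValueError("sequence must be uppercase ACGT")
    sites = []
    start = seq.find(enzyme.recognition)
    while start != -1:
        sites.append(start)
        start = seq.find(enzyme.recognition, start + 1)
    return sites


def digest_molecule(seq: str, methyl_mask: dict[int, bool] | None,
                    enzyme: Enzyme) -> list[int]:
    """Cut positions (fragment boundaries) for one molecule.

    ``methyl_mask`` maps recognition-site starts to methylation state; DpnI
    cuts only where the mask is true, PvuII cuts every site.  A mask key that
    is not a recognition-site start is an error.
    """
    sites = find_sites(seq, enzyme)
    site_set = set(sites)
    if methyl_mask:
        bad = [k for k in methyl_mask if k not in site_set]
        if bad:
            raise SiteError(f"mask keys {bad} are not {enzyme.name} sites")
    if enzyme.requires_m6a:
        mask = methyl_mask or {}
        cut_sites = [s for s in sites if mask.get(s, False)]
    else:
        cut_sites = sites
    return [s + enzyme.cut_offset for s in cut_sites]


def fragments(seq: str, cuts: list[int]) -> list[str]:
    """Split a molecule at the given cut positions."""
    bounds = [0, *sorted(cuts), len(seq)]
    return [seq[a:b] for a, b in zip(bounds, bounds[1:]) if b > a]


# ---------------------------------------------------------------------------
# junction-primer design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionPrimer:
    sequence: str
    linker_tail: str
    genomic_head: str
    unique: bool


def _genome_occurrences(build: GenomeBuild, probe: str) -> int:
    """Overlapping occurrences of probe on either strand of the genome."""
    if not probe:
        return 0
    rc = reverse_complement(probe)
    total = 0
    for seq in build.sequences.values():
        for pat in {probe, rc}:
            start = seq.find(pat)
            while start != -1:
                total += 1
                start = seq.find(pat, start + 1)
    return total


def design_junction_primer(build: GenomeBuild, site: tuple[str, int],
                           enzyme: Enzyme = DPNI, linker: Linker = Linker(),
                           tail_len: int = 22, head_len: int = 3) -> JunctionPrimer:
    """Forward primer = 3' ``tail_len`` bases of the linker primer arm +
    first ``head_len`` genomic bases 3' of the cut.  The head plus the next
    10 genomic bases must occur exactly once in the genome for the primer to
    be flagged unique (TE-targeted designs are intentionally non-unique)."""
    chrom, start = site
    seq = build.sequences[chrom]
    if seq[start:start + len(enzyme.recognition)] != enzyme.recognition:
        raise SiteError(f"{chrom}:{start} is not a {enzyme.name} site")
    cut = start + enzyme.cut_offset
    if cut + head_len > len(seq):
        raise SiteError("genomic head extends past the chromosome end")
    head = seq[cut:cut + head_len]
    tail = linker.arm_b[-tail_len:] if tail_len > 0 else ""
    probe = seq[cut:cut + head_len + 10]
    unique = head_len > 0 and _genome_occurrences(build, probe) == 1
    return JunctionPrimer(tail + head, tail, head, unique)


@dataclass(frozen=True)
class AssayDesign:
    """One family's DpnI target site plus the PvuII internal control."""

    family_id: str
    chrom: str
    site_start: int
    enzyme: Enzyme
    forward_primer: JunctionPrimer
    reverse_primer: str
    control_chrom: str
    control_site_start: int
    control_forward: JunctionPrimer
    cycles: int = 32
    efficiency: float = 1.0
    saturation: float = 1e15


def _first_motif_site(build: GenomeBuild, family_id: str, motif: str) -> tuple[str, int]:
    for f in build.features:
        if f.kind == "te_copy" and f.family_id == family_id:
            idx = build.feature_sequence(f).find(motif)
            if idx != -1:
                return f.chrom, f.start + idx
    raise SiteError(f"no {motif} site found in plus-strand copies of {family_id}")


def default_dpni_design(build: GenomeBuild, family_id: str,
                        control_family: str = "Tc3-like",
                        cycles: int = 32) -> AssayDesign:
    """The packaged assay for one TE family: DpnI target site in the family's
    planted GATCC context (head TCC, tail 22 nt), PvuII control site in the
    control family (head CTG, tail 30 nt)."""
    chrom, start = _first_motif_site(build, family_id, "GATCC")
    fwd = design_junction_primer(build, (chrom, start), DPNI, tail_len=22, head_len=3)
    cut = start + DPNI.cut_offset
    rev = reverse_complement(build.sequences[chrom][cut + 60:cut + 80])
    c_chrom, c_start = _first_motif_site(build, control_family, PVUII.recognition)
    c_fwd = design_junction_primer(build, (c_chrom, c_start), PVUII,
                                   tail_len=30, head_len=3)
    return AssayDesign(family_id, chrom, start, DPNI, fwd, rev,
                       c_chrom, c_start, c_fwd, cycles=cycles)


# ---------------------------------------------------------------------------
# assay simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayReadout:
    target_signal: float
    control_signal: float

    @property
    def relative_level(self) -> float:
        return self.target_signal / self.control_signal


def simulate_assay(pool: MoleculePool, design: AssayDesign,
                   cycles: int | None = None,
                   efficiency: float | None = None) -> AssayReadout:
    """Digest--ligate--amplify one pool.

    Target templates are the methylated molecules (DpnI cuts them; ligation
    efficiency is 1); control templates are all molecules (PvuII cuts
    everything).  Both amplify by (1+efficiency)^cycles, capped at the
    saturation level; in the linear regime the relative level equals the
    pool's methylated fraction exactly.
    """
    cycles = design.cycles if cycles is None else cycles
    eff = design.efficiency if efficiency is None else efficiency
    if not (0 < eff <= 1):
        raise ValueError("efficiency must be in (0, 1]")
    amp = (1.0 + eff) ** cycles
    target = min(int(pool.methylated.sum()) * amp, design.saturation)
    control = min(pool.n_molecules * amp, design.saturation)
    if control >= design.saturation and target < design.saturation:
        warnings.warn("control saturated while target is not: the relative "
                      "level underestimates the methylated fraction",
                      stacklevel=2)
    return AssayReadout(target, control)


def fold_change(readout_old: AssayReadout, readout_young: AssayReadout) -> float:
    """Aged/young ratio of relative levels (same design assumed)."""
    if readout_young.relative_level == 0:
        raise UndefinedRatioError("young relative level is zero")
    return readout_old.relative_level / readout_young.relative_level


# ---------------------------------------------------------------------------
# excision-junction assay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExcisionDesign:
    feature_id: str
    junction_primer: str      # upstream-flank tail + downstream-flank head
    upstream_flank: str
    downstream_flank: str
    internal_forward: str     # control pair inside the intact element
    internal_reverse: str


def design_excision_primers(build: GenomeBuild, te_copy: Feature,
                            flank_len: int = 20) -> ExcisionDesign:
    """Junction primer spanning the element's flanks; amplifies only after
    excision juxtaposes them.  Both flanks must be unique in the genome."""
    seq = build.sequences[te_copy.chrom]
    if te_copy.start < flank_len or te_copy.end + flank_len > len(seq):
        raise SiteError("element too close to the chromosome end for flanks")
    up = seq[te_copy.start - flank_len:te_copy.start]
    down = seq[te_copy.end:te_copy.end + flank_len]
    for name, flank in (("upstream", up), ("downstream", down)):
        if _genome_occurrences(build, flank) != 1:
            raise SpecificityError(f"{name} flank of {te_copy.feature_id} is "
                                   "not unique in the genome")
    element = build.feature_sequence(te_copy)
    internal_fwd = element[10:30]
    internal_rev = reverse_complement(element[-30:-10])
    return ExcisionDesign(te_copy.feature_id, up + down, up, down,
                          internal_fwd, internal_rev)


def excised_locus_sequence(build: GenomeBuild, te_copy: Feature,
                           context: int = 200) -> str:
    """The locus after precise excision: flanking context juxtaposed."""
    seq = build.sequences[te_copy.chrom]
    a = max(te_copy.start - context, 0)
    b = min(te_copy.end + context, len(seq))
    return seq[a:te_copy.start] + seq[te_copy.end:b]


def detect_excision(pool: MoleculePool, design: ExcisionDesign,
                    threshold: float = 0.005) -> tuple[bool, float]:
    """Excision readout: estimated excised fraction and whether the junction
    product is above the gel detection threshold."""
    estimate = pool.excised_fraction
    return estimate >= threshold, estimate
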