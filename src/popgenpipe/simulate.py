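"""Forward Wright-Fisher simulation of a small diploid cohort.

This module generates the synthetic inputs the analysis pipeline consumes:
a reference sequence, a sample of diploid genotypes segregating under a
known demography and selection regime, an outgroup sequence at a known
divergence, and exon/CNE annotation. Because every quantity downstream
(diversity, divergence, Tajima's D, LD decay) has a known generative value
here, the simulator doubles as ground truth for the test-suite.

Model summary
-------------
* Discrete, non-overlapping generations; diploid population of size N per
  epoch (epochs listed most ancient first; the oldest epoch is run for at
  least ``burn_in_factor * N`` generations before later epochs apply).
* Mutation: per-haplotype per-generation count ~ Poisson(mu*L) at uniform
  positions. Infinite-sites is approximated by flip-on-remutation, so every
  segregating site stays biallelic.
* Recombination: Poisson(rec*L) crossovers per transmitted gamete.
* Selection: viability selection, multiplicative across sites with
  semidominance h = 0.5; diploid fitness = prod(1 - s * dosage / 2).
* Outgroup: each position substituted independently with probability
  1 - exp(-2*mu*t_split); at selected positions the substitution rate is
  scaled by the relative fixation probability of a semidominant deleterious
  allele, gamma/(e^gamma - 1) with gamma = Ne*s.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DemographyModel",
    "SelectionMap",
    "Population",
    "SimulatedCohort",
    "Annotation",
    "ExonInterval",
    "CohortConfig",
    "simulate_wright_fisher",
    "sample_cohort",
    "emit_outgroup",
    "synthesize_annotation",
    "make_reference",
    "simulate_cohort",
    "write_fixture",
    "fixation_rate_ratio",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")

NEUTRAL, EXON_LIKE, CNE_LIKE = 0, 1, 2
_LABEL_NAMES = {NEUTRAL: "neutral", EXON_LIKE: "exon", CNE_LIKE: "cne"}


@dataclass(frozen=True)
class DemographyModel:
    """Piecewise-constant diploid population sizes, most ancient first.

    Each epoch is ``(N, duration_generations)``. The oldest epoch is also
    the burn-in epoch: it runs for at least ``burn_in_factor * N``
    generations (see :func:`simulate_wright_fisher`).
    """

    epochs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(self.epochs) == 0:
            raise ValueError("demography needs at least one epoch")
        for n, dur in self.epochs:
            if n < 2:
                raise ValueError(f"population size {n} < 2")
            if dur < 1:
                raise ValueError(f"epoch duration {dur} < 1")
        object.__setattr__(self, "epochs", tuple((int(n), int(d)) for n, d in self.epochs))

    @classmethod
    def constant(cls, n: int, duration: int = 1) -> "DemographyModel":
        return cls(((n, duration),))


@dataclass
class SelectionMap:
    """Per-position selection coefficient (fitness deficit of the derived
    allele; 0 = neutral) and site-class label."""

    s: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.s.shape != self.labels.shape:
            raise ValueError("s and labels must have the same length")
        if np.any(self.s < 0):
            raise ValueError("deleterious model requires s >= 0")
        if np.any(self.s[self.labels == NEUTRAL] != 0):
            raise ValueError("neutral positions must have s = 0")

    def __len__(self) -> int:
        return len(self.s)

    @classmethod
    def neutral(cls, length: int) -> "SelectionMap":
        return cls(np.zeros(length), np.zeros(length, dtype=np.int8))

    @classmethod
    def from_annotation(
        cls,
        length: int,
        annotation: "Annotation",
        s_exon: float = 0.0,
        s_cne: float = 0.0,
    ) -> "SelectionMap":
        s = np.zeros(length)
        labels = np.zeros(length, dtype=np.int8)
        for ex in annotation.exons:
            labels[ex.start:ex.end] = EXON_LIKE
            s[ex.start:ex.end] = s_exon
        for c0, c1 in annotation.cnes:
            labels[c0:c1] = CNE_LIKE
            s[c0:c1] = s_cne
        return cls(s, labels)


@dataclass
class Population:
    """Haplotypes of a whole simulated population at segregating sites.

    ``haplotypes`` is a (2N, S) 0/1 matrix of derived-allele indicators at
    the sorted 0-based ``positions``. Sites where the derived allele fixed
    or was lost are dropped as they arise.
    """

    length: int
    positions: np.ndarray
    haplotypes: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


@dataclass(frozen=True)
class ExonInterval:
    """A single-CDS exon: 0-based half-open interval with strand and phase."""

    start: int
    end: int
    strand: str = "+"
    phase: int = 0
    transcript_id: str = ""


@dataclass
class Annotation:
    exons: list[ExonInterval] = field(default_factory=list)
    cnes: list[tuple[int, int]] = field(default_factory=list)

    def exon_intervals(self) -> list[tuple[int, int]]:
        return [(e.start, e.end) for e in self.exons]


@dataclass
class SimulatedCohort:
    """A sampled diploid cohort with everything the pipeline needs.

    ``genotypes`` holds dosages in {0, 1, 2} with -1 for missing calls;
    the invariant ``genotypes[i, p] == haplotypes[2i, p] + haplotypes[2i+1, p]``
    holds wherever the genotype is not masked.
    """

    reference: str
    outgroup: str
    positions: np.ndarray          # 0-based segregating positions
    haplotypes: np.ndarray         # (2n, S) derived indicators
    genotypes: np.ndarray          # (n, S) dosage, -1 missing
    depths: np.ndarray             # (n, S) per-sample read depth
    quals: np.ndarray              # (S,) site quality score
    annotation: Annotation
    truth: dict

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def alt_alleles(self) -> np.ndarray:
        """Derived base at each segregating position (deterministic: next base
        in ACGT order after the reference base)."""
        ref = np.frombuffer(self.reference.encode(), dtype="S1")[self.positions]
        idx = np.searchsorted(BASES, ref)
        return BASES[(idx + 1) % 4]


def _validate_rates(mu: float, rec: float) -> None:
    for name, r in (("mu", mu), ("rec", rec)):
        if not np.isfinite(r) or not (0 <= r < 1):
            raise ValueError(f"{name} must be finite and in [0, 1), got {r}")


def _prune(positions: np.ndarray, hap: np.ndarray):
    """Drop columns where the derived allele is lost or fixed."""
    counts = hap.sum(axis=0)
    keep = (counts > 0) & (counts < hap.shape[0])
    if keep.all():
        return positions, hap
    return positions[keep], hap[:, keep]


def simulate_wright_fisher(
    L: int,
    demography: DemographyModel,
    mu: float,
    rec: float,
    selection: SelectionMap | None = None,
    seed: int = 0,
    burn_in_factor: int = 10,
) -> Population:
    """Run a forward Wright-Fisher simulation and return the final population.

    The oldest epoch runs for ``max(duration, burn_in_factor * N)``
    generations so the population reaches mutation-drift(-selection)
    equilibrium before any later epoch applies.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    _validate_rates(mu, rec)
    if selection is not None and len(selection) != L:
        raise ValueError("selection map length must equal L")
    rng = np.random.default_rng(seed)

    sel_s = None
    if selection is not None and np.any(selection.s > 0):
        sel_s = selection.s

    epochs = list(demography.epochs)
    n0 = epochs[0][0]
    schedule = [(n0, max(epochs[0][1], burn_in_factor * n0))]
    schedule += epochs[1:]

    positions = np.empty(0, dtype=np.int64)
    hap = np.zeros((2 * n0, 0), dtype=np.uint8)

    for n_dip, duration in schedule:
        for _ in range(duration):
            positions, hap = _wf_generation(L, n_dip, mu, rec, sel_s, positions, hap, rng)

    positions, hap = _prune(positions, hap)
    return Population(length=L, positions=positions, haplotypes=hap)


def _fitness(hap: np.ndarray, positions: np.ndarray, sel_s: np.ndarray) -> np.ndarray:
    s_at = sel_s[positions]
    sel_cols = np.nonzero(s_at > 0)[0]
    n = hap.shape[0] // 2
    if sel_cols.size == 0:
        return np.ones(n)
    dos = hap[0::2][:, sel_cols].astype(np.float64) + hap[1::2][:, sel_cols]
    with np.errstate(divide="ignore"):
        logw = np.log(1.0 - s_at[sel_cols] * dos / 2.0).sum(axis=1)
    w = np.exp(logw)
    w[~np.isfinite(w)] = 0.0
    if w.sum() <= 0:
        raise RuntimeError("population fitness collapsed to zero")
    return w


def _wf_generation(L, n_child, mu, rec, sel_s, positions, hap, rng):
    n_parent = hap.shape[0] // 2
    if sel_s is not None and positions.size:
        w = _fitness(hap, positions, sel_s)
        p = w / w.sum()
        parents = rng.choice(n_parent, size=2 * n_child, p=p)
    else:
        parents = rng.integers(0, n_parent, size=2 * n_child)

    which = rng.integers(0, 2, size=2 * n_child)
    new = hap[2 * parents + which]

    # crossovers are rare at test scale; handle them per-gamete
    if rec > 0 and positions.size:
        nxo = rng.poisson(rec * L, size=2 * n_child)
        for g in np.nonzero(nxo)[0]:
            breaks = np.sort(rng.integers(0, L, size=nxo[g]))
            seg = np.searchsorted(breaks, positions, side="right") % 2
            a = hap[2 * parents[g] + which[g]]
            b = hap[2 * parents[g] + 1 - which[g]]
            new[g] = np.where(seg == 0, a, b)
    new = np.ascontiguousarray(new)

    n_mut = rng.poisson(2 * n_child * mu * L)
    if n_mut:
        mut_pos = rng.integers(0, L, size=n_mut)
        mut_hap = rng.integers(0, 2 * n_child, size=n_mut)
        idx = np.searchsorted(positions, mut_pos)
        hit = (idx < positions.size) & (positions[np.minimum(idx, positions.size - 1)] == mut_pos) \
            if positions.size else np.zeros(n_mut, dtype=bool)
        # re-mutation at a segregating site flips the allele
        for k in np.nonzero(hit)[0]:
            col = idx[k]
            new[mut_hap[k], col] ^= 1
        fresh_pos = mut_pos[~hit]
        fresh_hap = mut_hap[~hit]
        if fresh_pos.size:
            uniq, inv = np.unique(fresh_pos, return_inverse=True)
            add = np.zeros((2 * n_child, uniq.size), dtype=np.uint8)
            for k in range(fresh_pos.size):
                add[fresh_hap[k], inv[k]] ^= 1
            positions = np.concatenate([positions, uniq])
            new = np.concatenate([new, add], axis=1)
            order = np.argsort(positions, kind="stable")
            positions = positions[order]
            new = new[:, order]

    return _prune(positions, new)


def fixation_rate_ratio(gamma: float | np.ndarray) -> float | np.ndarray:
    """Fixation probability of a semidominant deleterious mutation relative
    to a neutral one: gamma / (e^gamma - 1), gamma = Ne * s.

    Approaches 1 as gamma -> 0 and decays ~ gamma * e^-gamma for strongly
    selected alleles, so divergence at selected sites is suppressed far more
    than diversity.
    """
    g = np.asarray(gamma, dtype=float)
    out = np.where(g == 0, 1.0, g / np.expm1(np.where(g == 0, 1.0, g)))
    return float(out) if np.isscalar(gamma) else out


def emit_outgroup(
    reference: str,
    mu: float,
    t_split: float,
    seed: int = 0,
    selection: SelectionMap | None = None,
    ne: float | None = None,
) -> str:
    """Substitute reference positions independently under a Jukes-Cantor
    process with expected substitution load ``2 * mu_eff * t_split`` per
    site (two lineages since the split): the probability of OBSERVING a
    different base is (3/4) * (1 - exp(-(4/3) * 2 * mu_eff * t_split)),
    which is 1 - exp(-2 mu t) up to the small multiple-hit correction and
    saturates at 3/4; the substituted base is uniform among the three
    alternatives.

    With a selection map and an Ne, mu_eff at selected positions is scaled
    by :func:`fixation_rate_ratio`, so that selected site classes show
    reduced divergence as well as reduced diversity.
    """
    if t_split < 0:
        raise ValueError("t_split must be >= 0")
    if not np.isfinite(mu) or mu < 0:
        raise ValueError("mu must be finite and >= 0")
    rng = np.random.default_rng(seed)
    ref = np.frombuffer(reference.encode(), dtype="S1").copy()
    L = ref.size
    mu_eff = np.full(L, mu)
    if selection is not None:
        if len(selection) != L:
            raise ValueError("selection map length must equal reference length")
        if ne is None:
            raise ValueError("ne is required when a selection map is given")
        mu_eff *= fixation_rate_ratio(ne * selection.s)
    p_sub = 0.75 * -np.expm1(-(4.0 / 3.0) * 2.0 * mu_eff * t_split)
    hit = rng.random(L) < p_sub
    if hit.any():
        idx = np.searchsorted(BASES, ref[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        ref[hit] = BASES[(idx + shift) % 4]
    return ref.tobytes().decode()


def synthesize_annotation(
    L: int,
    exon_density: float,
    cne_density: float,
    seed: int = 0,
    exon_len_mean: int = 300,
    cne_len_mean: int = 120,
    clustering: float = 0.0,
    cluster_scale: float = 2000.0,
    max_tries: int = 20000,
) -> Annotation:
    """Place non-overlapping exon and CNE intervals on [0, L).

    Exon lengths are multiples of 3 (single-CDS transcripts, phase 0) so
    degeneracy classification applies directly. With ``clustering`` > 0 a
    CNE is, with that probability, placed at an exponentially distributed
    gap (scale ``cluster_scale``) from a random exon edge, reproducing the
    overrepresentation of conserved noncoding elements near genes;
    ``clustering = 0`` places CNEs uniformly.
    """
    for name, dens in (("exon_density", exon_density), ("cne_density", cne_density)):
        if not (0 <= dens < 1):
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)

    def draw_intervals(total_bp, mean_len, forbidden, multiple3, placer=None):
        placed: list[tuple[int, int]] = []
        occupied = sorted(forbidden)
        covered = 0
        tries = 0
        while covered < total_bp and tries < max_tries:
            tries += 1
            length = int(rng.poisson(mean_len)) or mean_len
            if multiple3:
                length = max(30, 3 * round(length / 3))
            else:
                length = max(20, length)
            if placer is not None:
                start = placer(length)
            else:
                start = int(rng.integers(0, max(1, L - length)))
            if start is None or start < 0 or start + length > L:
                continue
            end = start + length
            if any(s < end and start < e for s, e in occupied):
                continue
            placed.append((start, end))
            occupied.append((start, end))
            occupied.sort()
            covered += length
        if covered < 0.5 * total_bp:
            raise ValueError("requested density infeasible for L")
        return placed

    exon_iv = []
    if exon_density > 0:
        exon_iv = draw_intervals(int(exon_density * L), exon_len_mean, [], True)
    exons = [
        ExonInterval(s, e, strand="+", phase=0, transcript_id=f"t{i:04d}")
        for i, (s, e) in enumerate(sorted(exon_iv))
    ]

    cnes: list[tuple[int, int]] = []
    if cne_density > 0:
        def cne_placer(length):
            if exons and clustering > 0 and rng.random() < clustering:
                ex = exons[int(rng.integers(0, len(exons)))]
                gap = int(rng.exponential(cluster_scale)) + 1
                if rng.random() < 0.5:
                    return ex.start - gap - length
                return ex.end + gap
            return int(rng.integers(0, max(1, L - length)))

        cnes = sorted(
            draw_intervals(int(cne_density * L), cne_len_mean, exon_iv, False, cne_placer)
        )
    return Annotation(exons=exons, cnes=cnes)


_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


def make_reference(L: int, annotation: Annotation, seed: int = 0) -> str:
    """Random base sequence with every exon span rewritten as a valid CDS
    (ATG, internal non-stop codons, terminal stop) on its strand."""
    rng = np.random.default_rng(seed)
    ref = BASES[rng.integers(0, 4, size=L)].copy()
    for ex in annotation.exons:
        n_codon = (ex.end - ex.start) // 3
        internal = rng.choice(len(_NONSTOP_CODONS), size=max(0, n_codon - 2))
        cds = "ATG" + "".join(_NONSTOP_CODONS[i] for i in internal) + "TAA"
        if ex.strand == "-":
            cds = cds[::-1].translate(str.maketrans("ACGT", "TGCA"))
        ref[ex.start:ex.end] = np.frombuffer(cds.encode(), dtype="S1")
    return ref.tobytes().decode()


def sample_cohort(
    population: Population,
    n_sample: int,
    missing_rate: float = 0.0,
    seed: int = 0,
    reference: str | None = None,
    outgroup: str | None = None,
    annotation: Annotation | None = None,
    truth: dict | None = None,
    depth_mean: float = 30.0,
    depth_dispersion: float = 5.0,
    qual_low_prob: float = 0.03,
    qual_low: tuple[float, float] = (5.0, 22.0),
    qual_high: tuple[float, float] = (30.0, 1000.0),
) -> SimulatedCohort:
    """Draw ``n_sample`` diploids (haplotypes paired without replacement),
    mask genotypes at ``missing_rate``, and attach read depths
    (negative binomial: mean ``depth_mean``, dispersion ``depth_dispersion``)
    and site QUAL scores (mixture: with probability ``qual_low_prob`` uniform
    on ``qual_low``, else uniform on ``qual_high``) so every filter in the
    pipeline has something to act on.
    """
    if 2 * n_sample > population.n_haplotypes:
        raise ValueError("n_sample too large for population")
    if not (0 <= missing_rate <= 1):
        raise ValueError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(population.n_haplotypes, size=2 * n_sample, replace=False)
    hap = population.haplotypes[chosen]
    # restrict to sites segregating in the sample
    counts = hap.sum(axis=0)
    keep = (counts > 0) & (counts < 2 * n_sample)
    hap = hap[:, keep]
    positions = population.positions[keep]
    S = positions.size

    genotypes = (hap[0::2].astype(np.int8) + hap[1::2].astype(np.int8))
    if missing_rate > 0:
        miss = rng.random(genotypes.shape) < missing_rate
        genotypes = np.where(miss, np.int8(-1), genotypes)

    # NB parameterised by mean m and dispersion k: p = k/(k+m)
    p = depth_dispersion / (depth_dispersion + depth_mean)
    depths = rng.negative_binomial(depth_dispersion, p, size=genotypes.shape)
    low = rng.random(S) < qual_low_prob
    quals = np.where(
        low,
        rng.uniform(*qual_low, size=S),
        rng.uniform(*qual_high, size=S),
    )

    if reference is None:
        reference = make_reference(population.length, annotation or Annotation(), seed + 1)
    return SimulatedCohort(
        reference=reference,
        outgroup=outgroup if outgroup is not None else reference,
        positions=positions,
        haplotypes=hap,
        genotypes=genotypes,
        depths=depths,
        quals=quals,
        annotation=annotation or Annotation(),
        truth=truth or {},
    )


@dataclass
class CohortConfig:
    """End-to-end simulation settings.

    Defaults emulate the study conditions the pipeline targets: a cohort of
    12 diploids, neutral per-site diversity near 0.15%, a recent ~10-fold
    contraction, selected exon-like and CNE-like sites with Ne*s ~ 5, and
    an outgroup at ~14% divergence.
    """

    L: int = 100_000
    n_sample: int = 12
    epochs: tuple[tuple[int, int], ...] = ((120, 1), (12, 12))
    mu: float = 3.125e-6         # theta = 4*N*mu = 0.0015 per site in the old epoch
    rec: float = 3.125e-6
    s_exon: float = 0.042        # Ne*s ~ 5 with the ancestral N = 120
    s_cne: float = 0.042
    exon_density: float = 0.05
    cne_density: float = 0.03
    clustering: float = 0.5
    cluster_scale: float = 2000.0
    divergence_target: float = 0.142
    missing_rate: float = 0.02
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def selection_from_degeneracy(
    length: int,
    annotation: Annotation,
    reference: str,
    s_exon: float,
    s_cne: float,
) -> SelectionMap:
    """Selection map respecting codon degeneracy: 0-fold exonic positions
    get ``s_exon``, 2-fold positions ``s_exon / 2``, 4-fold positions are
    neutral (mutations there are synonymous), CNE positions get ``s_cne``.
    This is what makes 4-fold sites and CNE flanks behave as the neutral
    standard downstream."""
    from .site_classes import CLASS_CODES, SiteClassMap, Transcript, classify_degeneracy

    transcripts = [
        Transcript(ex.transcript_id or f"t{i}", ex.strand, [(ex.start, ex.end)])
        for i, ex in enumerate(annotation.exons)
    ]
    site_map = classify_degeneracy(transcripts, reference,
                                   SiteClassMap.empty(length))
    s = np.zeros(length)
    labels = np.zeros(length, dtype=np.int8)
    for ex in annotation.exons:
        labels[ex.start:ex.end] = EXON_LIKE
    s[site_map.codes == CLASS_CODES["fold0"]] = s_exon
    s[site_map.codes == CLASS_CODES["fold2"]] = s_exon / 2.0
    for c0, c1 in annotation.cnes:
        labels[c0:c1] = CNE_LIKE
        s[c0:c1] = s_cne
    s[labels == NEUTRAL] = 0.0
    return SelectionMap(s, labels)


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Annotation -> reference -> selection -> Wright-Fisher -> cohort ->
    outgroup, all from one config + seed. Deterministic given the config."""
    cfg = config
    annotation = synthesize_annotation(
        cfg.L, cfg.exon_density, cfg.cne_density, seed=cfg.seed,
        clustering=cfg.clustering, cluster_scale=cfg.cluster_scale,
    )
    reference = make_reference(cfg.L, annotation, seed=cfg.seed + 1)
    selection = selection_from_degeneracy(cfg.L, annotation, reference,
                                          cfg.s_exon, cfg.s_cne)
    demography = DemographyModel(cfg.epochs)
    pop = simulate_wright_fisher(
        cfg.L, demography, cfg.mu, cfg.rec, selection, seed=cfg.seed + 2
    )
    ne_anc = demography.epochs[0][0]
    # invert the Jukes-Cantor observed-difference formula so that neutral
    # divergence ~ divergence_target
    p = min(cfg.divergence_target, 0.74)
    lam = -0.75 * np.log1p(-(4.0 / 3.0) * p)
    t_split = lam / (2 * cfg.mu)
    outgroup = emit_outgroup(
        reference, cfg.mu, t_split, seed=cfg.seed + 3,
        selection=selection, ne=ne_anc,
    )
    truth = {"config": cfg.to_dict(), "t_split": float(t_split), "ne_ancestral": ne_anc}
    return sample_cohort(
        pop, cfg.n_sample, cfg.missing_rate, seed=cfg.seed + 4,
        reference=reference, outgroup=outgroup, annotation=annotation, truth=truth,
    )


def _write_fasta(path: Path, name: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def write_fixture(cohort: SimulatedCohort, out_dir: str | Path, chrom: str = "chr1") -> dict:
    """Write the cohort as the file bundle the pipeline reads.

    Emits: multi-sample VCF v4.2 (GT:DP per sample, site QUAL, INFO key F),
    reference and outgroup FASTA, exon GFF3 (CDS features with strand and
    phase), CNE BED3, and a truth JSON that replays to the identical cohort.
    VCF positions are 1-based; BED/GFF follow their own conventions.
    """
    from .popgen_stats import inbreeding_coefficient_from_dosages

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "reference": out / "reference.fa",
        "outgroup": out / "outgroup.fa",
        "gff3": out / "exons.gff3",
        "cne_bed": out / "cnes.bed",
        "truth": out / "truth.json",
    }
    _write_fasta(paths["reference"], chrom, cohort.reference)
    _write_fasta(paths["outgroup"], chrom, cohort.outgroup)

    n = cohort.n_samples
    samples = [f"S{i:02d}" for i in range(n)]
    alt = cohort.alt_alleles
    ref_arr = np.frombuffer(cohort.reference.encode(), dtype="S1")
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={len(cohort.reference)}>\n")
        fh.write('##INFO=<ID=F,Number=1,Type=Float,Description="Inbreeding coefficient">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        gt_strings = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        for col, pos in enumerate(cohort.positions):
            dos = cohort.genotypes[:, col]
            f = inbreeding_coefficient_from_dosages(dos, min_samples=10)
            info = "." if f is None else f"F={f:.4f}"
            fields = [
                chrom, str(int(pos) + 1), ".",
                ref_arr[pos].decode(), alt[col].decode(),
                f"{cohort.quals[col]:.2f}", "PASS", info, "GT:DP",
            ]
            fields += [
                f"{gt_strings[int(d)]}:{int(cohort.depths[i, col])}"
                for i, d in enumerate(dos)
            ]
            fh.write("\t".join(fields) + "\n")

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for ex in cohort.annotation.exons:
            fh.write(
                f"{chrom}\tpopgenpipe\tCDS\t{ex.start + 1}\t{ex.end}\t.\t"
                f"{ex.strand}\t{ex.phase}\tID=cds_{ex.transcript_id};"
                f"Parent={ex.transcript_id}\n"
            )
    with open(paths["cne_bed"], "w") as fh:
        for s, e in cohort.annotation.cnes:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
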