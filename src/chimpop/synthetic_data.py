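"""Synthetic inputs with the statistical structure the pipeline assumes.

Everything here is seeded and byte-reproducible: two tandem paralog pools
with allelic SNP diversity, chimeras formed by a single 5'→3' crossover,
diploid regional populations with configurable genotype-class frequencies,
and a variant matrix with a planted low-diversity / rare-variant-excess
footprint.  Planted truths (breakpoints, genotype classes, sweep center)
are recorded on every output for downstream oracle tests.

The sweep generator is a phenomenological thinning + site-frequency-skew
model, not a coalescent: sites near the planted center are removed with
probability ``s * exp(-|x - center| / L)`` and surviving nearby sites draw
their derived-allele count from a singleton-inflated frequency spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chimera_detect import GenotypeRecord, PrimerPair, reverse_complement
from .errors import ParameterError
from .io_formats import AlleleSequence, SampleMetadata, VariantMatrix

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

GENOTYPE_CLASSES = ("B3/B3", "B3/par", "par/par")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SweepParams:
    segment_length: int = 150_000
    site_density: float = 0.02
    sample_n: int = 12
    sweep_center: int = 75_000
    decay_length: float = 2_500.0
    strength: float = 0.9

    def validate(self) -> None:
        if not (0.0 <= self.strength <= 1.0):
            raise ParameterError(f"sweep strength must be in [0,1], got {self.strength}")
        if self.decay_length <= 0 or self.segment_length <= 0:
            raise ParameterError("segment_length and decay_length must be positive")
        if self.sample_n < 2:
            raise ParameterError("sample_n must be >= 2 diploids")
        if self.segment_length < 10 * self.decay_length:
            logger.warning(
                "segment_length %d < 10*decay_length: sweep footprint fills the segment",
                self.segment_length,
            )


@dataclass
class RegionConfig:
    name: str
    n_individuals: int
    #: probabilities for (B3/B3, B3/par, par/par)
    genotype_frequencies: tuple[float, float, float]
    #: mixture over chimeric allele names for chimeric chromosomes
    allele_mixture: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if abs(sum(self.genotype_frequencies) - 1.0) > 1e-9:
            raise ParameterError(
                f"region {self.name!r}: genotype frequencies must sum to 1"
            )
        if self.allele_mixture and abs(sum(self.allele_mixture.values()) - 1.0) > 1e-9:
            raise ParameterError(f"region {self.name!r}: allele mixture must sum to 1")


@dataclass
class SimulationConfig:
    seed: int = 0
    paralog_length: int = 3_000
    intron_span: tuple[int, int] = (1_800, 2_400)
    theta_site: float = 0.01
    n_alleles_per_parent: int = 8
    parent_divergence: float = 0.05
    #: (allele_name, crossover_position) pairs; positions must be 5' of the intron
    breakpoints: list[tuple[str, int]] = field(default_factory=list)
    regions: list[RegionConfig] = field(default_factory=list)
    sweep: SweepParams = field(default_factory=SweepParams)
    primer_length: int = 20
    #: spacer inserted between the tandem genes on a parental chromosome; kept
    #: longer than any plausible max amplicon so cross-gene pairings never amplify
    tandem_spacer: int = 6_000

    def validate(self) -> None:
        if not (0.0 <= self.theta_site < 0.5):
            raise ParameterError(
                f"theta_site must be in [0, 0.5), got {self.theta_site}"
            )
        if not (0.0 <= self.parent_divergence <= 1.0):
            raise ParameterError("parent_divergence must be in [0,1]")
        s, e = self.intron_span
        if not (0 <= s < e <= self.paralog_length):
            raise ParameterError("intron_span must lie within the paralog")
        for name, pos in self.breakpoints:
            if not (0 <= pos <= self.paralog_length):
                raise ParameterError(f"breakpoint {name!r} at {pos} outside paralog")
            if pos > s:
                raise ParameterError(
                    f"breakpoint {name!r} at {pos} must be 5' of the intron start {s}"
                )
        for region in self.regions:
            region.validate()
        self.sweep.validate()


def default_breakpoints(config: SimulationConfig, n: int = 8,
                        rng: Optional[np.random.Generator] = None) -> list[tuple[str, int]]:
    """Evenly spread crossover positions 5' of the intron, one per allele name."""
    lo = config.primer_length + 30
    hi = config.intron_span[0] - 30
    positions = np.linspace(lo, hi, n).astype(int)
    return [(f"v{i + 1}", int(p)) for i, p in enumerate(positions)]


# ---------------------------------------------------------------------------
# sequence-level generators
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, prob: float,
            protected: Optional[np.ndarray] = None) -> np.ndarray:
    """Independent per-site substitution to a uniformly different base."""
    out = seq.copy()
    if prob <= 0:
        return out
    hit = rng.random(len(seq)) < prob
    if protected is not None:
        hit &= ~protected
    idx = np.nonzero(hit)[0]
    if idx.size:
        # shift by 1..3 in base space guarantees a different base
        cur = np.searchsorted(BASES, out[idx])
        out[idx] = BASES[(cur + rng.integers(1, 4, size=idx.size)) % 4]
    return out


def _to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode("ascii")


def _primer_footprints(config: SimulationConfig) -> dict[str, tuple[int, int]]:
    """Fixed primer windows near the gene ends, protected from mutation.

    ``fwd`` is near the 5' end (upstream of every crossover), ``rev`` near
    the 3' end (downstream of the intron), so the diagnostic primer pairs
    bind every allele of their parent pool.
    """
    p = config.primer_length
    return {
        "fwd": (10, 10 + p),
        "rev": (config.paralog_length - 10 - p, config.paralog_length - 10),
    }


def sample_parental_alleles(
    config: SimulationConfig,
) -> tuple[list[AlleleSequence], list[AlleleSequence]]:
    """Draw the two parental allele pools from per-parent ancestral sequences.

    A single random ancestor is drawn for parent B1; the B2 ancestor differs
    from it at a ``parent_divergence`` fraction of sites (informative sites
    for breakpoint mapping).  Each allele then derives from its ancestor by
    independent per-site substitution with probability ``theta_site``.
    Primer footprints are excluded from all substitutions.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    L = config.paralog_length
    fp = _primer_footprints(config)
    protected = np.zeros(L, dtype=bool)
    for s, e in fp.values():
        protected[s:e] = True

    b1_anc = _random_seq(rng, L)
    b2_anc = b1_anc.copy()
    n_div = int(round(config.parent_divergence * L))
    divergeable = np.nonzero(~protected)[0]
    div_sites = rng.choice(divergeable, size=min(n_div, divergeable.size), replace=False)
    cur = np.searchsorted(BASES, b2_anc[div_sites])
    b2_anc[div_sites] = BASES[(cur + rng.integers(1, 4, size=div_sites.size)) % 4]

    # primer footprints: conserved within a pool but densely different between
    # the parents (incl. the 3'-terminal bases) so each parent's primers bind
    # only its own pool even under mismatch-tolerant matching
    for fs, fe in fp.values():
        idx = np.append(np.arange(fs, fe, 2), fe - 1)
        cur = np.searchsorted(BASES, b2_anc[idx])
        b2_anc[idx] = BASES[(cur + 1) % 4]

    s, e = config.intron_span
    b1_features = [("exon", 0, s), ("intron", s, e), ("exon", e, L)]
    b2_features = [("exon", 0, L)]

    b1_pool, b2_pool = [], []
    for i in range(config.n_alleles_per_parent):
        b1_pool.append(AlleleSequence(
            id=f"B1_a{i}", gene_label="B1",
            sequence=_to_str(_mutate(rng, b1_anc, config.theta_site, protected)),
            features=list(b1_features),
        ))
    for i in range(config.n_alleles_per_parent):
        b2_pool.append(AlleleSequence(
            id=f"B2_a{i}", gene_label="B2",
            sequence=_to_str(_mutate(rng, b2_anc, config.theta_site, protected)),
            features=list(b2_features),
        ))
    logger.info(
        "sample_parental_alleles: %d+%d alleles, length %d, seed %d",
        len(b1_pool), len(b2_pool), L, config.seed,
    )
    b1_pool[0].annotations["ancestor"] = _to_str(b1_anc)
    b2_pool[0].annotations["ancestor"] = _to_str(b2_anc)
    return b1_pool, b2_pool


def make_chimera(
    b2_allele: AlleleSequence,
    b1_allele: AlleleSequence,
    crossover_position: int,
    name: str,
) -> AlleleSequence:
    """Join a 5' B2 segment to a 3' B1 segment at ``crossover_position``.

    The true breakpoint and the parent allele ids are recorded in the
    returned annotations for oracle use.  Positions 0 and the full length
    are allowed as degenerate boundaries (pure-B1 / pure-B2 output).
    """
    if len(b1_allele) != len(b2_allele):
        raise ParameterError("parent alleles must share a coordinate frame")
    L = len(b1_allele)
    if not (0 <= crossover_position <= L):
        raise ParameterError(
            f"crossover_position {crossover_position} outside [0, {L}]"
        )
    seq = b2_allele.sequence[:crossover_position] + b1_allele.sequence[crossover_position:]
    features = [
        (k, s, e) for (k, s, e) in b1_allele.features if k == "intron"
    ]
    return AlleleSequence(
        id=name,
        gene_label="B3",
        sequence=seq,
        features=features,
        annotations={
            "true_breakpoint": crossover_position,
            "b1_parent": b1_allele.id,
            "b2_parent": b2_allele.id,
        },
    )


def make_chimera_pool(
    config: SimulationConfig,
    b1_pool: Sequence[AlleleSequence],
    b2_pool: Sequence[AlleleSequence],
) -> list[AlleleSequence]:
    """One chimeric allele per configured breakpoint, parents drawn at random."""
    rng = np.random.default_rng([config.seed, 23])
    breakpoints = config.breakpoints or default_breakpoints(config)
    pool = []
    for name, pos in breakpoints:
        b1 = b1_pool[rng.integers(len(b1_pool))]
        b2 = b2_pool[rng.integers(len(b2_pool))]
        pool.append(make_chimera(b2, b1, pos, name))
    return pool


def design_primers(
    config: SimulationConfig,
    b1_pool: Sequence[AlleleSequence],
    b2_pool: Sequence[AlleleSequence],
) -> dict[str, PrimerPair]:
    """Diagnostic primer pairs taken from the parental ancestral footprints.

    Roles follow the wet-lab assay layout: ``screening`` pairs the B2 forward
    primer with the B1 reverse primer (amplifies only the chimera),
    ``reciprocal`` pairs B1 forward with B2 reverse (amplifies only the
    reciprocal-crossover product), and the two ``parental_*`` pairs amplify
    within a single parental gene.
    """
    b1_anc = b1_pool[0].annotations.get("ancestor")
    b2_anc = b2_pool[0].annotations.get("ancestor")
    if b1_anc is None or b2_anc is None:
        raise ParameterError("pools lack ancestor annotations; use sample_parental_alleles")
    fp = _primer_footprints(config)
    fs, fe = fp["fwd"]
    rs, re_ = fp["rev"]
    b1f, b2f = b1_anc[fs:fe], b2_anc[fs:fe]
    b1r, b2r = reverse_complement(b1_anc[rs:re_]), reverse_complement(b2_anc[rs:re_])
    return {
        "screening": PrimerPair("screening", forward=b2f, reverse=b1r),
        "parental_b1": PrimerPair("parental_b1", forward=b1f, reverse=b1r),
        "parental_b2": PrimerPair("parental_b2", forward=b2f, reverse=b2r),
        "reciprocal": PrimerPair("reciprocal", forward=b1f, reverse=b2r),
    }


# ---------------------------------------------------------------------------
# population-level generator
# ---------------------------------------------------------------------------

def simulate_population(
    config: SimulationConfig,
    parent_pools: tuple[Sequence[AlleleSequence], Sequence[AlleleSequence]],
    chimera_pool: Sequence[AlleleSequence],
):
    """Draw diploid individuals per region with the configured class frequencies.

    Returns ``(metadata, truth_records, templates)`` where ``templates`` maps
    sample_id to its two haplotype template sequences: a chimeric chromosome
    carries one chimeric allele; a parental chromosome carries one B1 and one
    B2 allele in tandem (B1 upstream, spacer, B2 downstream) so that the
    cross-gene screening/reciprocal primer pairings never converge within a
    plausible amplicon length.
    """
    config.validate()
    b1_pool, b2_pool = parent_pools
    if not b1_pool or not b2_pool or not chimera_pool:
        raise ParameterError("allele pools must be non-empty")
    by_name = {c.id: c for c in chimera_pool}
    rng = np.random.default_rng([config.seed, 37])

    metadata: list[SampleMetadata] = []
    truth: list[GenotypeRecord] = []
    templates: dict[str, tuple[AlleleSequence, AlleleSequence]] = {}

    for region in config.regions:
        mixture_names = list(region.allele_mixture) or [c.id for c in chimera_pool]
        unknown = [n for n in mixture_names if n not in by_name]
        if unknown:
            raise ParameterError(
                f"region {region.name!r}: unknown allele names {unknown}"
            )
        mixture_p = (
            np.array([region.allele_mixture[n] for n in mixture_names])
            if region.allele_mixture
            else np.full(len(mixture_names), 1.0 / len(mixture_names))
        )
        classes = rng.choice(
            len(GENOTYPE_CLASSES),
            size=region.n_individuals,
            p=np.asarray(region.genotype_frequencies, dtype=float),
        )
        for i, cls_idx in enumerate(classes):
            sid = f"{region.name}_{i:04d}"
            cls = GENOTYPE_CLASSES[cls_idx]
            n_chimeric = 2 - cls_idx  # B3/B3 -> 2, B3/par -> 1, par/par -> 0
            haps = []
            allele_calls = []
            for h in range(2):
                if h < n_chimeric:
                    allele = by_name[mixture_names[rng.choice(len(mixture_names), p=mixture_p)]]
                    allele_calls.append(allele.id)
                    haps.append(AlleleSequence(
                        id=f"{sid}_h{h + 1}",
                        gene_label="B3",
                        region_label=region.name,
                        sequence=allele.sequence,
                        features=list(allele.features),
                        annotations={"carries_b3": True, "allele": allele.id},
                    ))
                else:
                    b1 = b1_pool[rng.integers(len(b1_pool))]
                    b2 = b2_pool[rng.integers(len(b2_pool))]
                    spacer = _to_str(_random_seq(rng, config.tandem_spacer))
                    haps.append(AlleleSequence(
                        id=f"{sid}_h{h + 1}",
                        gene_label="other",
                        region_label=region.name,
                        sequence=b1.sequence + spacer + b2.sequence,
                        annotations={
                            "carries_b3": False,
                            "b1_allele": b1.id,
                            "b2_allele": b2.id,
                        },
                    ))
            metadata.append(SampleMetadata(sid, "target", region.name, "field"))
            truth.append(GenotypeRecord(
                sample_id=sid,
                genotype_class=cls,
                allele_calls=sorted(allele_calls),
                evidence=[],
            ))
            templates[sid] = (haps[0], haps[1])

    logger.info(
        "simulate_population: %d individuals across %d regions, seed %d",
        len(metadata), len(config.regions), config.seed,
    )
    return metadata, truth, templates


# ---------------------------------------------------------------------------
# variant-matrix generator with planted sweep footprint
# ---------------------------------------------------------------------------

def simulate_variant_matrix(config: SimulationConfig) -> VariantMatrix:
    """Variant matrix over a reference segment with a planted sweep footprint.

    Candidate sites arrive at ``site_density`` per bp; each is retained with
    probability ``1 - s * exp(-|x - center| / L)``.  Retained sites draw a
    derived-allele count k from a 1/k spectrum over k = 1 .. 2n-1, except
    within distance L of the center where the singleton mass is boosted by
    ``1 + 4 s`` and renormalized.  Haplotypes are paired consecutively into
    diploids.  The planted center is recorded in ``annotations``.
    """
    config.validate()
    sw = config.sweep
    rng = np.random.default_rng([config.seed, 53])
    n_hap = 2 * sw.sample_n

    n_candidates = rng.poisson(sw.site_density * sw.segment_length)
    positions = np.unique(rng.integers(1, sw.segment_length + 1, size=n_candidates))
    dist = np.abs(positions - sw.sweep_center)
    keep = rng.random(positions.size) >= sw.strength * np.exp(-dist / sw.decay_length)
    positions = positions[keep]
    dist = dist[keep]

    k_values = np.arange(1, n_hap)
    base_w = 1.0 / k_values
    base_p = base_w / base_w.sum()
    boost_w = base_w.copy()
    boost_w[0] *= 1.0 + 4.0 * sw.strength
    boost_p = boost_w / boost_w.sum()

    m = positions.size
    near = dist <= sw.decay_length
    k = np.empty(m, dtype=np.int64)
    k[near] = rng.choice(k_values, size=int(near.sum()), p=boost_p)
    k[~near] = rng.choice(k_values, size=int((~near).sum()), p=base_p)
    # rank trick: per site, the k haplotypes with the smallest random draws carry
    rank = rng.random((m, n_hap)).argsort(axis=1).argsort(axis=1)
    hap = (rank < k[:, None]).astype(np.int8)
    genotypes = (hap[:, 0::2] + hap[:, 1::2]).T.copy()

    matrix = VariantMatrix(
        sample_ids=[f"sim_{i:03d}" for i in range(sw.sample_n)],
        positions=positions,
        genotypes=genotypes,
        segment_length=sw.segment_length,
        annotations={"sweep_center": sw.sweep_center, "seed": config.seed},
    )
    logger.info(
        "simulate_variant_matrix: %d sites over %d bp (%d candidates), seed %d",
        matrix.n_sites, sw.segment_length, n_candidates, config.seed,
    )
    return matrix


# ---------------------------------------------------------------------------
# intron alignments for the origins analysis
# ---------------------------------------------------------------------------

def simulate_intron_alignment(
    seed: int,
    n_parent: int = 8,
    n_chimera: int = 6,
    n_columns: int = 300,
    clade_divergence: float = 0.10,
    tip_noise: float = 0.01,
    donors: int = 1,
) -> list[AlleleSequence]:
    """Aligned intron set with a planted single- or two-donor chimera origin.

    The parental pool is split into two subclades separated by
    ``clade_divergence``.  With ``donors=1`` all chimeric introns descend
    from a single ancestor well separated from both subclades (monophyletic
    truth); with ``donors=2`` half the chimeric introns descend from each
    subclade ancestor (paraphyletic truth).
    """
    if donors not in (1, 2):
        raise ParameterError("donors must be 1 or 2")
    rng = np.random.default_rng([seed, 71])
    root = _random_seq(rng, n_columns)
    anc_a = _mutate(rng, root, clade_divergence)
    anc_b = _mutate(rng, root, clade_divergence)

    out: list[AlleleSequence] = []
    for i in range(n_parent):
        anc = anc_a if i < n_parent // 2 else anc_b
        out.append(AlleleSequence(
            id=f"B1_i{i}", gene_label="B1",
            sequence=_to_str(_mutate(rng, anc, tip_noise)),
        ))
    if donors == 1:
        chim_anc = _mutate(rng, root, clade_divergence * 2.0)
        ancestors = [chim_anc] * n_chimera
    else:
        ancestors = [
            anc_a if i < n_chimera // 2 else anc_b for i in range(n_chimera)
        ]
    for i, anc in enumerate(ancestors):
        out.append(AlleleSequence(
            id=f"B3_i{i}", gene_label="B3",
            sequence=_to_str(_mutate(rng, anc, tip_noise)),
            annotations={"donors": donors},
        ))
    return out
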