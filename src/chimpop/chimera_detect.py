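"""In-silico PCR screen and diploid genotype classification.

A haplotype template "carries" the chimeric gene iff the screening primer
pair (parent-2 forward + parent-1 reverse) predicts a product on it.  The
classifier screens the two haplotype templates of a diploid separately and
pools the band evidence, mirroring what the gel assay would show.

Primer matching is exact by default; up to ``max_mismatch`` internal
mismatches may be allowed, but the three 3'-terminal primer bases must
always match exactly (extension requirement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import FormatError, ParameterError
from .io_formats import AlleleSequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PRIMER_ROLES = ("screening", "parental_b1", "parental_b2", "reciprocal")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PrimerPair:
    """Forward/reverse primer pair, both written 5'->3' per PCR convention."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 12:
                raise ParameterError(f"{self.name}: {label} primer shorter than 12 nt")
            if set(p) - set("ACGT"):
                raise ParameterError(f"{self.name}: {label} primer has non-ACGT bases")


@dataclass
class AmpliconCall:
    template_id: str
    product: bool
    product_length: Optional[int] = None
    product_sequence: Optional[str] = None
    primer_pair: str = ""

    def __post_init__(self) -> None:
        if self.product:
            if self.product_sequence is None or self.product_length is None:
                raise ParameterError("present product requires length and sequence")
            if len(self.product_sequence) != self.product_length:
                raise ParameterError("product_length != len(product_sequence)")
        else:
            if self.product_sequence is not None or self.product_length is not None:
                raise ParameterError("absent product must carry no length/sequence")


@dataclass
class GenotypeRecord:
    sample_id: str
    genotype_class: str  # B3/B3, B3/par, par/par, unknown
    allele_calls: list[str] = field(default_factory=list)
    evidence: list[AmpliconCall] = field(default_factory=list)


# ---------------------------------------------------------------------------
# primer-site search
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan(template: np.ndarray, primer: np.ndarray, max_mismatch: int,
          anchor_left: bool) -> list[tuple[int, int]]:
    """All primer occurrences; (start, mismatches). The 3 bases at the 3' end
    (right end of the site when ``anchor_left`` is False, left end otherwise)
    must match exactly."""
    n, m = template.size, primer.size
    if m > n:
        return []
    width = n - m + 1
    mism = np.zeros(width, dtype=np.int32)
    for j in range(m):
        mism += template[j: j + width] != primer[j]
    anchor = np.zeros(width, dtype=bool)
    anchor_cols = range(3) if anchor_left else range(m - 3, m)
    for j in anchor_cols:
        anchor |= template[j: j + width] != primer[j]
    hits = np.nonzero((mism <= max_mismatch) & ~anchor)[0]
    return [(int(p), int(mism[p])) for p in hits]


def find_primer_sites(
    template: str, primer: str, max_mismatch: int = 0
) -> list[tuple[int, str, int]]:
    """Occurrences of a primer on both strands of a template.

    Returns ``(position, strand, mismatches)`` triples where ``position`` is
    the primer's 5' end in forward-strand coordinates: the leftmost base of
    the site for '+' hits, the rightmost for '-' hits.
    """
    if max_mismatch < 0:
        raise ParameterError("max_mismatch must be >= 0")
    t = _encode(template)
    fwd = _encode(primer)
    out = [(pos, "+", mm) for pos, mm in _scan(t, fwd, max_mismatch, anchor_left=False)]
    rev_site = _encode(reverse_complement(primer))
    # on a '-' hit the primer's 3' end maps to the leftmost template base
    for pos, mm in _scan(t, rev_site, max_mismatch, anchor_left=True):
        out.append((pos + len(primer) - 1, "-", mm))
    out.sort(key=lambda x: (x[0], x[1]))
    return out


def predict_amplicon(
    template: Union[str, AlleleSequence],
    primer_pair: PrimerPair,
    max_len: int = 5000,
    max_mismatch: int = 0,
) -> AmpliconCall:
    """Predict the PCR product of a convergent primer pair on a template.

    A product exists iff a forward-strand hit of the forward primer lies 5'
    of a reverse-strand hit of the reverse primer within ``max_len``; the
    product spans both primers' 5' ends inclusive.  The shortest pairing
    wins.
    """
    if max_len <= 0:
        raise ParameterError("max_len must be positive")
    template_id = template.id if isinstance(template, AlleleSequence) else ""
    seq = template.sequence if isinstance(template, AlleleSequence) else template

    fwd_hits = [p for p, s, _ in find_primer_sites(seq, primer_pair.forward, max_mismatch)
                if s == "+"]
    rev_hits = [p for p, s, _ in find_primer_sites(seq, primer_pair.reverse, max_mismatch)
                if s == "-"]
    best: Optional[tuple[int, int]] = None
    rev_hits.sort()
    for f in fwd_hits:
        i = np.searchsorted(rev_hits, f + 1)
        if i < len(rev_hits):
            r = rev_hits[i]
            length = r - f + 1
            if length <= max_len and (best is None or length < best[0]):
                best = (length, f)
    if best is None:
        return AmpliconCall(template_id, False, primer_pair=primer_pair.name)
    length, f = best
    return AmpliconCall(
        template_id,
        True,
        product_length=length,
        product_sequence=seq[f: f + length],
        primer_pair=primer_pair.name,
    )


# ---------------------------------------------------------------------------
# genotype classification
# ---------------------------------------------------------------------------

def build_allele_catalog(
    chimera_pool: Sequence[AlleleSequence],
    screening_pair: PrimerPair,
    max_len: int = 5000,
) -> dict[str, str]:
    """Map each known chimeric allele's screening-product sequence to its name.

    Alleles whose products collide on sequence identity are dropped from the
    catalog (ambiguous call) with a warning.
    """
    catalog: dict[str, str] = {}
    collided: set[str] = set()
    for allele in chimera_pool:
        call = predict_amplicon(allele, screening_pair, max_len=max_len)
        if not call.product:
            logger.warning("allele %s yields no screening product", allele.id)
            continue
        key = call.product_sequence
        if key in catalog or key in collided:
            logger.warning("screening product collision for allele %s", allele.id)
            collided.add(key)
            catalog.pop(key, None)
            continue
        catalog[key] = allele.id
    return catalog


def classify_genotype(
    sample_id: str,
    templates: Sequence[AlleleSequence],
    screening_pair: PrimerPair,
    parental_pairs: Sequence[PrimerPair],
    reciprocal_pair: Optional[PrimerPair] = None,
    max_len: int = 5000,
    allele_catalog: Optional[dict[str, str]] = None,
) -> GenotypeRecord:
    """Classify a diploid from its two haplotype templates.

    A haplotype carries the chimera iff the screening pair amplifies on it;
    the class is B3/B3 (both), B3/par (one), par/par (neither carries but
    every parental pair amplifies on each non-carrier haplotype), otherwise
    unknown.  The reciprocal pair is screened and reported in the evidence.
    """
    if len(templates) != 2:
        raise ParameterError("diploid classification needs exactly two templates")
    evidence: list[AmpliconCall] = []
    carries: list[bool] = []
    parental_ok: list[bool] = []
    allele_calls: list[str] = []
    for hap in templates:
        screen = predict_amplicon(hap, screening_pair, max_len=max_len)
        evidence.append(screen)
        carries.append(screen.product)
        if screen.product and allele_catalog is not None:
            name = allele_catalog.get(screen.product_sequence)
            if name is not None:
                allele_calls.append(name)
        par_calls = [predict_amplicon(hap, p, max_len=max_len) for p in parental_pairs]
        evidence.extend(par_calls)
        parental_ok.append(all(c.product for c in par_calls))
        if reciprocal_pair is not None:
            evidence.append(predict_amplicon(hap, reciprocal_pair, max_len=max_len))

    n_b3 = sum(carries)
    if n_b3 == 2:
        cls = "B3/B3"
    elif n_b3 == 1:
        cls = "B3/par"
    elif all(
        ok for ok, c in zip(parental_ok, carries) if not c
    ) and not any(carries):
        cls = "par/par"
    else:
        cls = "unknown"
    return GenotypeRecord(
        sample_id=sample_id,
        genotype_class=cls,
        allele_calls=sorted(allele_calls),
        evidence=evidence,
    )


def classify_population(
    templates: dict[str, tuple[AlleleSequence, AlleleSequence]],
    primers: dict[str, PrimerPair],
    max_len: int = 5000,
    allele_catalog: Optional[dict[str, str]] = None,
) -> list[GenotypeRecord]:
    """Classify every sample with the standard four-role primer set."""
    missing = [r for r in ("screening", "parental_b1", "parental_b2") if r not in primers]
    if missing:
        raise ParameterError(f"primer roles missing: {missing}")
    parental = [primers["parental_b1"], primers["parental_b2"]]
    out = []
    for sid, haps in templates.items():
        out.append(classify_genotype(
            sid, haps, primers["screening"], parental,
            reciprocal_pair=primers.get("reciprocal"),
            max_len=max_len, allele_catalog=allele_catalog,
        ))
    logger.info("classify_population: %d samples screened", len(out))
    return out


# ---------------------------------------------------------------------------
# primer TSV I/O
# ---------------------------------------------------------------------------

def read_primers(path: Union[str, Path]) -> dict[str, PrimerPair]:
    """Read a primer TSV with columns name, forward, reverse, role."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["name", "forward", "reverse", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing primer columns {missing}")
    primers: dict[str, PrimerPair] = {}
    for row in df.itertuples(index=False):
        if row.role not in PRIMER_ROLES:
            raise FormatError(f"{path}: unknown primer role {row.role!r}")
        primers[row.role] = PrimerPair(row.name, row.forward, row.reverse)
    return primers


def write_primers(primers: dict[str, PrimerPair], path: Union[str, Path]) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [(p.name, p.forward, p.reverse, role) for role, p in primers.items()],
        columns=["name", "forward", "reverse", "role"],
    )
    df.to_csv(path, sep="\t", index=False)
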