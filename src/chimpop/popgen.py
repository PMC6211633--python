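"""Regional genotype/allele frequency tables and the sliding-window sweep scan.

π and Tajima's D are implemented directly from their definitions over the
diploid genotype matrix (no external popgen tool): per-site heterozygosity
is the unbiased mean pairwise difference 2j(n-j)/(n(n-1)) for j derived
copies among n haplotypes; windowed π divides the summed per-site values by
the full window span in bp; D contrasts the window's mean pairwise
difference count with S/a1 using Tajima's variance constants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chimera_detect import GenotypeRecord
from .errors import ParameterError
from .io_formats import SampleMetadata, VariantMatrix

logger = logging.getLogger(__name__)

GENOTYPE_CLASSES = ("B3/B3", "B3/par", "par/par")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTable:
    """Per-group genotype-class table and optional per-group allele table.

    Percentages are always recomputed from counts, never stored
    independently; ``carriage_pct`` is the share of individuals with at
    least one chimeric allele.
    """

    genotype_table: Optional[pd.DataFrame] = None
    allele_table: Optional[pd.DataFrame] = None


@dataclass
class WindowStat:
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    n_sites: int
    S: int
    theta_pi: float  # summed mean pairwise differences (count scale)
    pi: float        # per-site, over the window span
    tajima_d: Optional[float]
    partial: bool = False


@dataclass
class SweepReport:
    min_pi: float
    min_pi_window: tuple[int, int]
    mean_pi: float
    min_d: Optional[float]
    min_d_window: Optional[tuple[int, int]]
    mean_d: Optional[float]
    n_windows: int
    n_defined_d: int
    mean_pi_full_windows: Optional[float] = None


# ---------------------------------------------------------------------------
# metadata filtering and frequency tables
# ---------------------------------------------------------------------------

def species_filter(
    metadata: Sequence[SampleMetadata], target_species: str
) -> tuple[list[SampleMetadata], dict[str, int]]:
    """Keep records of the target species; tally every label seen."""
    counts: dict[str, int] = {}
    kept = []
    for m in metadata:
        counts[m.species_label] = counts.get(m.species_label, 0) + 1
        if m.species_label == target_species:
            kept.append(m)
    logger.info("species_filter: kept %d of %d records", len(kept), len(metadata))
    return kept, counts


def genotype_frequency_table(
    records: Sequence[GenotypeRecord],
    metadata: Optional[Sequence[SampleMetadata]] = None,
    group_by: str = "global",
) -> FrequencyTable:
    """Tabulate genotype-class counts and percentages per group.

    ``group_by='region'`` requires metadata for the region lookup; unknowns
    are tallied separately and excluded from the class denominator.
    """
    if group_by not in ("global", "region"):
        raise ParameterError("group_by must be 'global' or 'region'")
    region_of = {}
    if group_by == "region":
        if metadata is None:
            raise ParameterError("region grouping requires metadata")
        region_of = {m.sample_id: m.region for m in metadata}

    rows: dict[str, dict[str, int]] = {}
    for rec in records:
        group = region_of.get(rec.sample_id, "?") if group_by == "region" else "global"
        row = rows.setdefault(group, {c: 0 for c in GENOTYPE_CLASSES} | {"unknown": 0})
        key = rec.genotype_class if rec.genotype_class in GENOTYPE_CLASSES else "unknown"
        row[key] += 1

    out = []
    for group in sorted(rows):
        row = rows[group]
        n = sum(row[c] for c in GENOTYPE_CLASSES)
        carriage = row["B3/B3"] + row["B3/par"]
        out.append({
            "group": group,
            "n": n,
            "n_unknown": row["unknown"],
            **{f"count_{c}": row[c] for c in GENOTYPE_CLASSES},
            **{
                f"pct_{c}": (100.0 * row[c] / n if n else math.nan)
                for c in GENOTYPE_CLASSES
            },
            "carriage_pct": 100.0 * carriage / n if n else math.nan,
        })
    return FrequencyTable(genotype_table=pd.DataFrame(out))


def allele_frequency_table(
    records: Sequence[GenotypeRecord],
    metadata: Optional[Sequence[SampleMetadata]] = None,
    group_by: str = "global",
) -> FrequencyTable:
    """Per-group chimeric-allele counts, homozygote and heterozygote alleles
    summed (a v1 homozygote contributes two v1 copies)."""
    if group_by not in ("global", "region"):
        raise ParameterError("group_by must be 'global' or 'region'")
    region_of = {}
    if group_by == "region":
        if metadata is None:
            raise ParameterError("region grouping requires metadata")
        region_of = {m.sample_id: m.region for m in metadata}

    counts: dict[str, dict[str, int]] = {}
    for rec in records:
        group = region_of.get(rec.sample_id, "?") if group_by == "region" else "global"
        row = counts.setdefault(group, {})
        for name in rec.allele_calls:
            row[name] = row.get(name, 0) + 1

    out = []
    for group in sorted(counts):
        row = counts[group]
        total = sum(row.values())
        for name in sorted(row):
            out.append({
                "group": group,
                "allele": name,
                "count": row[name],
                "n_alleles": total,
                "pct": 100.0 * row[name] / total if total else math.nan,
            })
    return FrequencyTable(allele_table=pd.DataFrame(out))


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

def site_diversity(j: int, n: int) -> float:
    """Unbiased per-site heterozygosity for j derived copies among n haplotypes."""
    if n < 2:
        raise ParameterError("n must be >= 2")
    if not (0 <= j <= n):
        raise ParameterError(f"derived count {j} outside [0, {n}]")
    return 2.0 * j * (n - j) / (n * (n - 1))


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima's variance constants for n haplotypes."""
    if n < 4:
        raise ParameterError("Tajima's D requires n >= 4 haplotypes")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajima_d(theta_pi: float, S: int, n: int) -> Optional[float]:
    """Tajima's D from the summed pairwise-difference estimate and S.

    Returns None when S = 0 or the variance term vanishes.
    """
    if S == 0:
        return None
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return None
    return (theta_pi - S / k["a1"]) / math.sqrt(var)


# ---------------------------------------------------------------------------
# sliding-window scan
# ---------------------------------------------------------------------------

def sweep_scan(
    matrix: VariantMatrix,
    window_bp: int = 2500,
    step_bp: int = 1250,
) -> list[WindowStat]:
    """Sliding-window S, π and Tajima's D over the reference segment.

    Sites with any missing genotype are dropped (and logged) so the
    haplotype count n = 2N is constant, as Tajima's constants require.
    Windows tile [1, segment_length]; the final partial window is kept with
    its true span as the π denominator and flagged.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ParameterError("window_bp and step_bp must be positive")
    n = 2 * matrix.n_samples
    if n < 4:
        raise ParameterError("sweep_scan requires at least 2 diploids (n >= 4)")

    complete = ~np.any(matrix.genotypes < 0, axis=0)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("sweep_scan: dropped %d sites with missing genotypes", n_dropped)
    positions = matrix.positions[complete]
    derived = matrix.genotypes[:, complete].astype(np.int64).sum(axis=0)

    segregating = (derived > 0) & (derived < n)
    het = 2.0 * derived * (n - derived) / (n * (n - 1.0))

    stats: list[WindowStat] = []
    start = 1
    while start <= matrix.segment_length:
        end = min(start + window_bp - 1, matrix.segment_length)
        span = end - start + 1
        lo = np.searchsorted(positions, start, side="left")
        hi = np.searchsorted(positions, end, side="right")
        seg = segregating[lo:hi]
        S = int(seg.sum())
        theta_pi = float(het[lo:hi].sum())
        stats.append(WindowStat(
            start=start,
            end=end,
            n_sites=hi - lo,
            S=S,
            theta_pi=theta_pi,
            pi=theta_pi / span,
            tajima_d=tajima_d(theta_pi, S, n),
            partial=span < window_bp,
        ))
        start += step_bp
    logger.info("sweep_scan: %d windows (%d bp / %d bp step) over %d bp",
                len(stats), window_bp, step_bp, matrix.segment_length)
    return stats


def sweep_report(stats: Sequence[WindowStat]) -> SweepReport:
    """Summaries of a window scan; argmin ties broken by leftmost window.

    Mean D is over defined windows only and reported as None (never 0) when
    every window is undefined; the π mean is also given excluding partial
    windows since the all-window and full-window conventions can differ.
    """
    if not stats:
        raise ParameterError("sweep_report requires at least one window")
    pis = [w.pi for w in stats]
    i_min = int(np.argmin(pis))
    defined = [(i, w.tajima_d) for i, w in enumerate(stats) if w.tajima_d is not None]
    full = [w.pi for w in stats if not w.partial]
    if defined:
        j_min = min(defined, key=lambda t: t[1])[0]
        min_d = stats[j_min].tajima_d
        min_d_window = (stats[j_min].start, stats[j_min].end)
        mean_d = float(np.mean([d for _, d in defined]))
    else:
        min_d = min_d_window = mean_d = None
    return SweepReport(
        min_pi=stats[i_min].pi,
        min_pi_window=(stats[i_min].start, stats[i_min].end),
        mean_pi=float(np.mean(pis)),
        min_d=min_d,
        min_d_window=min_d_window,
        mean_d=mean_d,
        n_windows=len(stats),
        n_defined_d=len(defined),
        mean_pi_full_windows=float(np.mean(full)) if full else None,
    )


def windows_to_frame(stats: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "start": w.start, "end": w.end, "n_sites": w.n_sites, "S": w.S,
            "pi": w.pi, "tajima_d": w.tajima_d if w.tajima_d is not None else math.nan,
            "partial": w.partial,
        }
        for w in stats
    ])
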