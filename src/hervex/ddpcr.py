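"""Droplet digital PCR quantification and validation statistics.

A ddPCR reaction partitions template molecules across thousands of oil
emulsion droplets; each droplet reports only positive/negative after end-point
PCR.  Because droplets may hold zero, one, or several molecules, the mean
occupancy lambda is recovered from the positive fraction p by inverting the
Poisson zero class: ``lambda = -ln(1 - p)``; copies per reaction is then
``lambda x n_droplets``.

Target abundance is reported as copies per million copies of the RPL27
reference transcript; a small regularization constant (default 0.01) is added
to the per-million value before log2 so zero-copy wells stay finite.  The
treated-vs-untreated comparison is a classical paired t-test on per-donor
log2 values; the dose-response table reports per-dose log2 fold changes
against the untreated baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DropletAssay",
    "PoissonEstimate",
    "NormalizedExpression",
    "AssayOligo",
    "poisson_copies",
    "pool_replicates",
    "normalize_per_million",
    "paired_t",
    "dose_response",
    "oligo_qc",
    "amplicon_size",
    "process_wells",
    "TAQMAN_ASSAYS",
]

#: QX100-era droplet volume convention, nanoliters (only needed for per-µl
#: concentrations, not for per-reaction ratios)
DEFAULT_DROPLET_VOLUME_NL = 0.85


@dataclass
class DropletAssay:
    """One ddPCR well: droplet totals plus reaction metadata."""

    target: str
    n_droplets: int
    n_positive: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    sample: str | None = None
    donor: str | None = None
    dose_um: float | None = None
    replicate: int | None = None

    def __post_init__(self):
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if not 0 <= self.n_positive <= self.n_droplets:
            raise ValueError("need 0 <= n_positive <= n_droplets")


@dataclass(frozen=True)
class PoissonEstimate:
    """Mean copies per droplet and per reaction; saturated wells are flagged."""

    lambda_: float
    copies_per_reaction: float
    saturated: bool = False


@dataclass(frozen=True)
class NormalizedExpression:
    """Copies of target per million copies of reference, and its log2."""

    per_million: float
    log2_value: float
    regularization: float = 0.01


def poisson_copies(assay: DropletAssay) -> PoissonEstimate:
    """Invert Poisson occupancy: lambda = -ln(1 - positives/droplets).

    A fully positive well gives no finite estimate (every droplet occupied is
    consistent with any sufficiently large lambda) and is returned flagged
    with infinite values.
    """
    p = assay.n_positive / assay.n_droplets
    if p >= 1.0:
        warnings.warn(
            f"well for {assay.target!r} is saturated (all droplets positive); "
            "concentration is not estimable",
            stacklevel=2,
        )
        return PoissonEstimate(math.inf, math.inf, saturated=True)
    lam = -math.log1p(-p)
    return PoissonEstimate(lam, lam * assay.n_droplets, saturated=False)


def pool_replicates(assays: list[DropletAssay]) -> DropletAssay:
    """Merge replicate wells by pooling droplet counts (ML pooling).

    Summing droplets and positives before inverting the Poisson model is the
    maximum-likelihood combination; averaging per-well estimates is not.
    """
    if not assays:
        raise ValueError("no wells to pool")
    first = assays[0]
    if any(a.target != first.target for a in assays):
        raise ValueError("cannot pool wells with different targets")
    return DropletAssay(
        target=first.target,
        n_droplets=sum(a.n_droplets for a in assays),
        n_positive=sum(a.n_positive for a in assays),
        droplet_volume_nl=first.droplet_volume_nl,
        sample=first.sample,
        donor=first.donor,
        dose_um=first.dose_um,
    )


def normalize_per_million(
    target_copies: float, reference_copies: float, c: float = 0.01
) -> NormalizedExpression:
    """Target copies per million reference copies, log2 with +c regularization.

    ``per_million = target / reference * 1e6``; the constant is added to the
    per-million value before the log so a zero-copy target stays finite —
    the least-distorting placement that still prevents log(0).
    """
    if reference_copies <= 0:
        raise ValueError("reference copies must be > 0")
    if target_copies < 0:
        raise ValueError("target copies must be >= 0")
    per_million = target_copies / reference_copies * 1e6
    return NormalizedExpression(per_million, math.log2(per_million + c), c)


def paired_t(treated: np.ndarray, untreated: np.ndarray) -> tuple[float, float]:
    """Classical paired t-test on per-donor values, two-sided.

    Degenerate zero-variance nonzero differences give an infinite statistic;
    the p-value is then reported at the smallest positive float with a
    warning.  Identical inputs give t = 0, p = 1.
    """
    treated = np.asarray(treated, dtype=float)
    untreated = np.asarray(untreated, dtype=float)
    if treated.shape != untreated.shape or treated.size < 2:
        raise ValueError("need >= 2 matched pairs")
    diff = treated - untreated
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 1.0
        warnings.warn(
            "zero-variance nonzero paired differences: t is infinite, "
            "p reported at the machine floor",
            stacklevel=2,
        )
        sign = math.copysign(1.0, diff.mean())
        return sign * math.inf, float(np.nextafter(0.0, 1.0))
    t, p = stats.ttest_rel(treated, untreated)
    return float(t), float(p)


def dose_response(
    expression: pd.DataFrame,
    baseline_dose: float = 0.0,
) -> pd.DataFrame:
    """Per-dose log2 fold change against the untreated baseline.

    ``expression`` needs columns donor, target, dose_um, log2_value (one row
    per donor x target x dose).  Returns one row per donor x target x
    non-baseline dose with ``log2fc = log2(dose) - log2(baseline)`` and a
    per-curve flag marking monotone non-decreasing response across doses.
    """
    required = {"donor", "target", "dose_um", "log2_value"}
    missing = required - set(expression.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    rows = []
    for (donor, target), grp in expression.groupby(["donor", "target"]):
        base = grp[grp["dose_um"] == baseline_dose]
        if base.empty:
            raise ValueError(f"no untreated baseline for donor {donor!r}, target {target!r}")
        base_val = float(base["log2_value"].iloc[0])
        doses = grp[grp["dose_um"] != baseline_dose].sort_values("dose_um")
        lfcs = doses["log2_value"].to_numpy() - base_val
        monotone = bool(np.all(np.diff(lfcs) >= 0)) if len(lfcs) > 1 else True
        for dose, lfc in zip(doses["dose_um"], lfcs):
            rows.append(
                {
                    "donor": donor,
                    "target": target,
                    "dose_um": float(dose),
                    "log2fc": float(lfc),
                    "monotone_curve": monotone,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AssayOligo:
    """A primer or probe with its QC arithmetic (length, GC%)."""

    role: str  # forward | probe | reverse
    orientation: str  # sense | antisense
    sequence: str
    length: int
    gc_percent: float
    amplicon_size: int | None = None


def oligo_qc(
    sequence: str, role: str, orientation: str, amplicon_size: int | None = None
) -> AssayOligo:
    """Length and GC% of an assay oligo; GC rounded to 1 decimal."""
    seq = sequence.upper()
    if role not in {"forward", "probe", "reverse"}:
        raise ValueError(f"unknown oligo role {role!r}")
    if orientation not in {"sense", "antisense"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    if not seq or set(seq) - set("ACGT"):
        raise ValueError("oligo must be non-empty plain ACGT")
    gc = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
    return AssayOligo(role, orientation, seq, len(seq), round(gc, 1), amplicon_size)


def amplicon_size(forward: str, reverse: str, template: str) -> int | None:
    """Amplicon length on a template containing both primer sites.

    The forward primer must occur on the sense strand and the reverse primer
    (as given, antisense) must occur reverse-complemented downstream of it.
    Returns None when either site is absent (not evaluable on this template).
    """
    from hervex.refindex import reverse_complement

    template = template.upper()
    fstart = template.find(forward.upper())
    if fstart < 0:
        return None
    rsite = reverse_complement(reverse.upper())
    rstart = template.find(rsite, fstart)
    if rstart < 0:
        return None
    return rstart + len(rsite) - fstart


#: The custom TaqMan assay set targeting three LTR12 elements (rv_007357 has
#: two primer/probe sets covering its two expression peaks), with the
#: vendor-reported length, GC% and amplicon size for QC comparison.
TAQMAN_ASSAYS = [
    {"element": "rv_007357", "set": 1, "role": "forward", "orientation": "sense",
     "sequence": "GAGCGTATGGCGTTATGTAGTT", "reported_length": 22, "reported_gc": 45.5,
     "amplicon_size": 114},
    {"element": "rv_007357", "set": 1, "role": "probe", "orientation": "sense",
     "sequence": "TTGAGCCGATGAGATCGCTAAGCC", "reported_length": 24, "reported_gc": 54.0,
     "amplicon_size": 114},
    {"element": "rv_007357", "set": 1, "role": "reverse", "orientation": "antisense",
     "sequence": "AGCGGTATGTCCTCCCTTTA", "reported_length": 20, "reported_gc": 50.0,
     "amplicon_size": 114},
    {"element": "rv_007357", "set": 2, "role": "forward", "orientation": "sense",
     "sequence": "GGAGGAACGAAACACTCATCT", "reported_length": 21, "reported_gc": 47.6,
     "amplicon_size": 102},
    {"element": "rv_007357", "set": 2, "role": "probe", "orientation": "antisense",
     "sequence": "TGCAACTTTCACAGAGTCGTCTCACC", "reported_length": 26, "reported_gc": 50.0,
     "amplicon_size": 102},
    {"element": "rv_007357", "set": 2, "role": "reverse", "orientation": "antisense",
     "sequence": "CGTCTCACCCACTTCAGAAA", "reported_length": 20, "reported_gc": 50.0,
     "amplicon_size": 102},
    {"element": "rv_007420", "set": 1, "role": "forward", "orientation": "sense",
     "sequence": "GGTAGTGAGAGAGAACGGTATG", "reported_length": 22, "reported_gc": 50.0,
     "amplicon_size": 124},
    {"element": "rv_007420", "set": 1, "role": "probe", "orientation": "sense",
     "sequence": "TCCTCTGCTCATTCTGGTTGTGCT", "reported_length": 24, "reported_gc": 50.0,
     "amplicon_size": 124},
    {"element": "rv_007420", "set": 1, "role": "reverse", "orientation": "antisense",
     "sequence": "CTAAAGAGCTCCCACGGTATAG", "reported_length": 22, "reported_gc": 50.0,
     "amplicon_size": 124},
    {"element": "rv_010177", "set": 1, "role": "forward", "orientation": "sense",
     "sequence": "ACTCCAGACACACCGTCTTA", "reported_length": 20, "reported_gc": 50.0,
     "amplicon_size": 96},
    {"element": "rv_010177", "set": 1, "role": "probe", "orientation": "sense",
     "sequence": "ATTGGTAGCTTTCCCGAGTCAGCG", "reported_length": 24, "reported_gc": 54.0,
     "amplicon_size": 96},
    {"element": "rv_010177", "set": 1, "role": "reverse", "orientation": "antisense",
     "sequence": "TCATTCCATTCAGGTGGGTTC", "reported_length": 21, "reported_gc": 47.6,
     "amplicon_size": 96},
]


def process_wells(
    wells: pd.DataFrame, reference: str = "RPL27", c: float = 0.01
) -> pd.DataFrame:
    """Per-sample normalized expression from a well table.

    ``wells`` columns: sample, donor, dose_um, target, n_droplets,
    n_positive (one row per well; replicate wells are pooled).  Every sample
    must include a reference-target well.  Returns one row per sample x
    non-reference target with copies, per-million and log2 values.
    """
    required = {"sample", "donor", "dose_um", "target", "n_droplets", "n_positive"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")
    rows = []
    for sample, grp in wells.groupby("sample", sort=False):
        per_target: dict[str, float] = {}
        meta = grp.iloc[0]
        for target, tg in grp.groupby("target"):
            pooled = pool_replicates(
                [
                    DropletAssay(
                        target=str(target),
                        n_droplets=int(r.n_droplets),
                        n_positive=int(r.n_positive),
                        sample=str(sample),
                        donor=str(r.donor),
                        dose_um=float(r.dose_um),
                    )
                    for r in tg.itertuples()
                ]
            )
            per_target[str(target)] = poisson_copies(pooled).copies_per_reaction
        if reference not in per_target:
            raise ValueError(f"sample {sample!r} lacks reference target {reference!r}")
        ref_copies = per_target[reference]
        for target, copies in per_target.items():
            if target == reference:
                continue
            norm = normalize_per_million(copies, ref_copies, c=c)
            rows.append(
                {
                    "sample": sample,
                    "donor": meta["donor"],
                    "dose_um": float(meta["dose_um"]),
                    "target": target,
                    "copies_per_reaction": copies,
                    "reference_copies": ref_copies,
                    "per_million": norm.per_million,
                    "log2_value": norm.log2_value,
                }
            )
    return pd.DataFrame(rows)
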