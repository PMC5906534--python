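"""Synthetic data with known ground truth for every pipeline input.

The generator emulates the study design the pipeline targets: a library of a
few hundred retroviral elements in named families (with exact duplicate copies
and truncated fragments, to exercise the unique-assignment filter), donor-paired
negative-binomial expression where treatment log fold changes are concentrated
in designated families, stranded error-free 50 bp paired-end reads, and
Poisson partitioning of template molecules across ddPCR droplets.

All randomness flows from ``SimulationConfig.seed`` through a single
``numpy.random.Generator``; a fixed seed reproduces every artifact
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hervex.refindex import ElementLibrary, ElementRecord, reverse_complement

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_library",
    "simulate_counts",
    "simulate_reads",
    "write_paired_fastq",
    "simulate_droplets",
]

# default family labels cycle through names common in LTR catalogues; the first
# three carry the default injected treatment effects
_FAMILY_NAMES = [
    "LTR12",
    "LTR16C",
    "LTR33",
    "MLT1B",
    "THE1D",
    "MER41B",
    "LTR7",
    "MSTA",
    "LTR5_Hs",
    "MER21C",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the targeted experiment: four donors each measured
    untreated and after a 10 µM treatment, 50 bp reads, a library of ~300
    elements in 10 families, and strong (|log2FC| = 4) treatment effects
    injected into the LTR12 (up) and LTR16C/LTR33 (down) families.

    ``dispersion_trend`` maps abundance to NB dispersion as
    ``phi(mu) = asymptote + amplitude / mu``; the default is a constant
    dispersion of 0.1 (biological CV ~0.32, typical of primary-cell
    replicates).
    """

    n_families: int = 10
    elements_per_family: int = 30
    element_length_range: tuple[int, int] = (400, 2000)
    duplication_rate: float = 0.05
    fragment_rate: float = 0.05
    n_donors: int = 4
    conditions: tuple[tuple[str, float], ...] = (("untreated", 0.0), ("treated", 10.0))
    baseline_mean_log2: tuple[float, float] = (5.0, 2.0)  # (location, scale)
    dispersion_trend: dict = field(
        default_factory=lambda: {"asymptote": 0.1, "amplitude": 0.0}
    )
    treatment_lfc_map: dict = field(
        default_factory=lambda: {"LTR12": 4.0, "LTR16C": -4.0, "LTR33": -4.0}
    )
    donor_sd: float = 0.25
    read_length: int = 50
    fragment_length: int = 150
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.elements_per_family < 1 or self.n_donors < 1:
            raise ValueError("counts (families, elements, donors) must be >= 1")
        lo, hi = self.element_length_range
        if lo > hi:
            raise ValueError("element_length_range must be (min, max) with min <= max")
        if lo < self.read_length:
            raise ValueError(
                f"minimum element length {lo} is below read_length "
                f"{self.read_length}: such elements could not be read from"
            )
        if not 0.0 <= self.duplication_rate < 1.0:
            raise ValueError("duplication_rate must lie in [0, 1)")
        if not 0.0 <= self.fragment_rate < 1.0:
            raise ValueError("fragment_rate must lie in [0, 1)")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.donor_sd < 0:
            raise ValueError("donor_sd must be >= 0")
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions (a baseline and a treatment)")

    # -- JSON round trip -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["element_length_range"] = list(d["element_length_range"])
        d["baseline_mean_log2"] = list(d["baseline_mean_log2"])
        d["conditions"] = [list(c) for c in d["conditions"]]
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SimulationConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        d["element_length_range"] = tuple(d["element_length_range"])
        d["baseline_mean_log2"] = tuple(d["baseline_mean_log2"])
        d["conditions"] = tuple((str(lbl), float(dose)) for lbl, dose in d["conditions"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover.

    Filled in two stages: :func:`generate_library` records family membership,
    duplicate pairs and fragment parentage; :func:`simulate_counts` adds
    per-element baselines and true log2 fold changes plus the sample design.
    """

    family: dict[str, str] = field(default_factory=dict)
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    fragment_of: dict[str, str] = field(default_factory=dict)
    baseline_log2: dict[str, float] = field(default_factory=dict)
    lfc: dict[str, float] = field(default_factory=dict)
    design: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        """Per-element truth table (family, baseline, lfc, duplicate/fragment)."""
        dup_of = {b: a for a, b in self.duplicate_pairs}
        rows = []
        for eid, fam in self.family.items():
            rows.append(
                {
                    "element_id": eid,
                    "family": fam,
                    "baseline_log2": self.baseline_log2.get(eid, np.nan),
                    "true_lfc": self.lfc.get(eid, np.nan),
                    "duplicate_of": dup_of.get(eid, ""),
                    "fragment_of": self.fragment_of.get(eid, ""),
                }
            )
        return pd.DataFrame(rows).set_index("element_id")


def _family_labels(n: int) -> list[str]:
    labels = []
    for i in range(n):
        if i < len(_FAMILY_NAMES):
            labels.append(_FAMILY_NAMES[i])
        else:
            labels.append(f"FAM{i + 1}")
    return labels


def generate_library(
    config: SimulationConfig,
) -> tuple[ElementLibrary, GroundTruth]:
    """Generate the element library and its ground truth.

    Each family holds ``elements_per_family`` elements with ids
    ``rv_NNNNNN``.  After the first element of a family, each subsequent one
    is, with probability ``duplication_rate``, an exact byte-identical copy of
    an earlier original in the same family (distinct id), or with probability
    ``fragment_rate`` a truncated fragment of an earlier original — both
    produce reads that cannot be uniquely assigned and so exercise the
    multi-mapping discard rule.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.element_length_range
    labels = _family_labels(config.n_families)
    truth = GroundTruth()
    records: list[ElementRecord] = []
    serial = 0
    for fam in labels:
        originals: list[ElementRecord] = []
        for j in range(config.elements_per_family):
            serial += 1
            eid = f"rv_{serial:06d}"
            u = rng.random()
            if j > 0 and u < config.duplication_rate:
                parent = originals[rng.integers(len(originals))]
                seq = parent.sequence
                truth.duplicate_pairs.append((parent.element_id, eid))
            elif j > 0 and u < config.duplication_rate + config.fragment_rate:
                parent = originals[rng.integers(len(originals))]
                frac = rng.uniform(0.3, 0.8)
                flen = max(config.read_length, int(round(frac * parent.length)))
                start = rng.integers(0, parent.length - flen + 1)
                seq = parent.sequence[start : start + flen]
                truth.fragment_of[eid] = parent.element_id
            else:
                length = int(rng.integers(lo, hi + 1))
                seq = "".join(_BASES[rng.integers(0, 4, size=length)])
                rec = ElementRecord(eid, fam, seq)
                originals.append(rec)
                records.append(rec)
                truth.family[eid] = fam
                continue
            records.append(ElementRecord(eid, fam, seq))
            truth.family[eid] = fam
    return ElementLibrary(records), truth


def build_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: one row per donor x condition, with dose in µM."""
    rows = []
    for d in range(1, config.n_donors + 1):
        for label, dose in config.conditions:
            rows.append(
                {
                    "sample": f"D{d}_{label}",
                    "donor": f"D{d}",
                    "condition": label,
                    "dose_um": float(dose),
                }
            )
    return pd.DataFrame(rows).set_index("sample")


def simulate_counts(
    library: ElementLibrary,
    config: SimulationConfig,
    truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the true NB count matrix (elements x samples).

    For element g in sample i of donor d:
    ``count ~ NB(mean = 2^(baseline_g + donor_d + treated_i * lfc_g), phi_g)``
    with ``lfc_g`` looked up by family in ``treatment_lfc_map`` (0 elsewhere)
    and ``phi_g = asymptote + amplitude / 2^baseline_g``.  Donor offsets are
    drawn once per donor and shared across conditions — this is the pairing
    structure the design matrix must absorb.  A condition is "treated"
    whenever its dose is positive or its label is not ``untreated``.
    """
    if truth is None:
        truth = GroundTruth(family=dict(library.families))
    if rng is None:
        # decorrelated from the library stream so the same library can back
        # many count draws
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    design = build_design(config)
    truth.design = design

    eids = library.element_ids
    m = len(eids)
    loc, scale = config.baseline_mean_log2
    baseline = rng.normal(loc, scale, size=m)
    fams = library.families
    lfc = np.array([config.treatment_lfc_map.get(fams[e], 0.0) for e in eids])
    truth.baseline_log2 = dict(zip(eids, baseline.tolist()))
    truth.lfc = dict(zip(eids, lfc.tolist()))

    donor_offsets = {
        f"D{d}": rng.normal(0.0, config.donor_sd) for d in range(1, config.n_donors + 1)
    }
    asym = float(config.dispersion_trend.get("asymptote", 0.1))
    amp = float(config.dispersion_trend.get("amplitude", 0.0))
    mu_base = 2.0**baseline
    phi = asym + amp / mu_base

    counts = np.empty((m, len(design)), dtype=np.int64)
    for i, (sample, row) in enumerate(design.iterrows()):
        treated = (row["dose_um"] > 0) or (row["condition"] != "untreated")
        log2_mu = baseline + donor_offsets[row["donor"]] + (lfc if treated else 0.0)
        mu = 2.0**log2_mu
        col = np.empty(m, dtype=np.int64)
        over = phi > 0
        if over.any():
            col[over] = rng.negative_binomial(
                1.0 / phi[over], 1.0 / (1.0 + phi[over] * mu[over])
            )
        if (~over).any():
            col[~over] = rng.poisson(mu[~over])
        counts[:, i] = col
    df = pd.DataFrame(counts, index=pd.Index(eids, name="element_id"), columns=design.index)
    return df, truth


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = choices[rng.integers(3)].encode()
    return arr.tobytes().decode()


def simulate_reads(
    library: ElementLibrary,
    counts: pd.DataFrame,
    config: SimulationConfig,
    sample: str,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str, str]]:
    """Paired reads for one sample: ``(name, r1_seq, r2_seq)`` per count.

    R1 is a uniform-random length-L substring of the source element (sense
    strand); R2 is the reverse complement of a window whose start is offset by
    ``fragment_length`` (clipped to the element end).  Read names encode the
    source element for truth tracking: ``{sample}:{element}:{serial}``.
    Reads are error-free unless ``error_rate`` > 0.
    """
    if rng is None:
        # crc32 gives a stable per-sample stream regardless of interpreter hash seed
        sample_key = zlib.crc32(sample.encode()) % (2**31)
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2, sample_key)))
    L = config.read_length
    pairs: list[tuple[str, str, str]] = []
    col = counts[sample]
    for eid in counts.index:
        n = int(col.loc[eid])
        if n == 0:
            continue
        seq = library[eid].sequence
        if len(seq) < L:
            raise ValueError(f"element {eid} shorter than read length {L}")
        starts = rng.integers(0, len(seq) - L + 1, size=n)
        for k, s1 in enumerate(starts):
            s2 = min(int(s1) + config.fragment_length, len(seq) - L)
            r1 = seq[s1 : s1 + L]
            r2 = reverse_complement(seq[s2 : s2 + L])
            if config.error_rate > 0:
                r1 = _mutate(r1, config.error_rate, rng)
                r2 = _mutate(r2, config.error_rate, rng)
            pairs.append((f"{sample}:{eid}:{k}", r1, r2))
    return pairs


def write_paired_fastq(
    pairs: list[tuple[str, str, str]], r1_path: str | Path, r2_path: str | Path
) -> None:
    """Write read pairs as Phred+33 FASTQ (quality 'I' throughout)."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for name, r1, r2 in pairs:
            f1.write(f"@{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def simulate_droplets(
    copies_per_reaction: int,
    n_droplets: int,
    seed: int | np.random.Generator = 0,
    target: str = "target",
    **metadata,
):
    """Partition template molecules across droplets; count occupied droplets.

    Each of ``copies_per_reaction`` molecules lands in a uniformly random
    droplet (multinomial partitioning); a droplet is positive when it holds at
    least one molecule.  Returns a :class:`hervex.ddpcr.DropletAssay`.
    """
    from hervex.ddpcr import DropletAssay

    if copies_per_reaction < 0:
        raise ValueError("copies_per_reaction must be >= 0")
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    occupancy = rng.multinomial(int(copies_per_reaction), np.full(n_droplets, 1.0 / n_droplets))
    n_positive = int((occupancy > 0).sum())
    return DropletAssay(
        target=target, n_droplets=int(n_droplets), n_positive=n_positive, **metadata
    )
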