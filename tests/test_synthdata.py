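"""Generator contracts: determinism, ground-truth bookkeeping, NB statistics."""

import io
from collections import Counter

import numpy as np
import pytest

from hervex import refindex, synthdata
from hervex.synthdata import SimulationConfig


def fasta_bytes(library):
    buf = io.StringIO()
    for rec in library:
        buf.write(f">{rec.element_id}|{rec.family}\n{rec.sequence}\n")
    return buf.getvalue().encode()


class TestConfig:
    def test_rejects_elements_shorter_than_reads(self):
        with pytest.raises(ValueError, match="read_length"):
            SimulationConfig(element_length_range=(30, 100), read_length=50)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"duplication_rate": 1.0},
            {"duplication_rate": -0.1},
            {"n_donors": 0},
            {"donor_sd": -1.0},
            {"element_length_range": (500, 400)},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_json_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=7, treatment_lfc_map={"LTR12": 2.5})
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        assert SimulationConfig.from_json(path) == cfg


class TestLibrary:
    def test_duplication_disabled_all_sequences_distinct(self, small_library):
        library, truth = small_library
        seqs = [r.sequence for r in library]
        assert len(set(seqs)) == len(seqs)
        assert truth.duplicate_pairs == []

    def test_duplicate_pairs_match_sequence_hashes(self):
        # oracle: count repeated sequences in the emitted FASTA directly
        cfg = SimulationConfig(
            n_families=4, elements_per_family=25, duplication_rate=0.1,
            fragment_rate=0.0, seed=13,
        )
        library, truth = synthdata.generate_library(cfg)
        assert len(library) == 100
        dup_extra = sum(c - 1 for c in Counter(r.sequence for r in library).values())
        assert dup_extra == len(truth.duplicate_pairs)
        assert 3 <= len(truth.duplicate_pairs) <= 20  # ~10 expected at rate 0.1
        for parent, copy in truth.duplicate_pairs:
            assert library[parent].sequence == library[copy].sequence

    def test_fragments_are_substrings_of_parents(self):
        cfg = SimulationConfig(
            n_families=4, elements_per_family=25, duplication_rate=0.0,
            fragment_rate=0.15, seed=3,
        )
        library, truth = synthdata.generate_library(cfg)
        assert truth.fragment_of
        for frag, parent in truth.fragment_of.items():
            assert library[frag].sequence in library[parent].sequence
            assert library[frag].length >= cfg.read_length

    def test_same_seed_identical_fasta_bytes(self, small_config):
        lib1, _ = synthdata.generate_library(small_config)
        lib2, _ = synthdata.generate_library(small_config)
        assert fasta_bytes(lib1) == fasta_bytes(lib2)

    def test_different_seed_differs(self, small_config, small_library):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        lib2, _ = synthdata.generate_library(other)
        assert fasta_bytes(small_library[0]) != fasta_bytes(lib2)


class TestCounts:
    def test_null_family_log_ratio_near_zero(self):
        cfg = SimulationConfig(
            n_families=5, elements_per_family=60, duplication_rate=0,
            fragment_rate=0, treatment_lfc_map={}, baseline_mean_log2=(8.0, 0.5),
            seed=21,
        )
        library, _ = synthdata.generate_library(cfg)
        counts, truth = synthdata.simulate_counts(library, cfg)
        treated = truth.design[truth.design["condition"] == "treated"].index
        untreated = truth.design[truth.design["condition"] == "untreated"].index
        ratio = np.log2(counts[treated].mean(axis=1).mean() / counts[untreated].mean(axis=1).mean())
        assert abs(ratio) < 0.2

    def test_injected_lfc_recovered_in_family_means(self):
        # Monte-Carlo oracle: with lfc=3 at high baseline, the mean observed
        # treated/untreated log2 ratio over ~1000 element draws approaches 3
        cfg = SimulationConfig(
            n_families=1, elements_per_family=1000, duplication_rate=0,
            fragment_rate=0, treatment_lfc_map={"LTR12": 3.0},
            baseline_mean_log2=(9.0, 0.5), donor_sd=0.0, seed=5,
        )
        library, _ = synthdata.generate_library(cfg)
        counts, truth = synthdata.simulate_counts(library, cfg)
        treated = truth.design[truth.design["condition"] == "treated"].index
        untreated = truth.design[truth.design["condition"] == "untreated"].index
        ratios = np.log2(counts[treated].mean(axis=1) / counts[untreated].mean(axis=1))
        assert abs(ratios.mean() - 3.0) < 0.2

    def test_zero_dispersion_is_poisson(self):
        cfg = SimulationConfig(
            n_families=2, elements_per_family=400, duplication_rate=0,
            fragment_rate=0, treatment_lfc_map={},
            dispersion_trend={"asymptote": 0.0, "amplitude": 0.0},
            baseline_mean_log2=(7.0, 0.0), donor_sd=0.0, seed=9,
        )
        library, _ = synthdata.generate_library(cfg)
        counts, _ = synthdata.simulate_counts(library, cfg)
        vmr = counts.var(axis=1, ddof=1) / counts.mean(axis=1)
        assert abs(vmr.mean() - 1.0) < 0.15

    def test_overdispersion_exceeds_poisson(self):
        cfg = SimulationConfig(
            n_families=2, elements_per_family=400, duplication_rate=0,
            fragment_rate=0, treatment_lfc_map={},
            dispersion_trend={"asymptote": 0.3, "amplitude": 0.0},
            baseline_mean_log2=(7.0, 0.0), donor_sd=0.0, seed=9,
        )
        library, _ = synthdata.generate_library(cfg)
        counts, _ = synthdata.simulate_counts(library, cfg)
        vmr = (counts.var(axis=1, ddof=1) / counts.mean(axis=1)).mean()
        assert vmr > 5  # mu + phi mu^2 with mu=128, phi=0.3 -> VMR ~ 39

    def test_counts_deterministic(self, small_config, small_library):
        library, _ = small_library
        c1, _ = synthdata.simulate_counts(library, small_config)
        c2, _ = synthdata.simulate_counts(library, small_config)
        assert c1.equals(c2)


class TestReads:
    def test_pair_count_matches_counts_and_names_track_source(
        self, small_config, small_library
    ):
        library, _ = small_library
        counts, truth = synthdata.simulate_counts(library, small_config)
        sample = counts.columns[1]
        pairs = synthdata.simulate_reads(library, counts, small_config, sample)
        assert len(pairs) == counts[sample].sum()
        per_element = Counter(name.split(":")[1] for name, _, _ in pairs)
        for eid in counts.index:
            assert per_element.get(eid, 0) == counts.loc[eid, sample]

    def test_reads_relocate_in_source_element(self, small_config, small_library):
        # oracle substring scan: R1 forward, R2 reverse-complement
        library, _ = small_library
        counts, _ = synthdata.simulate_counts(library, small_config)
        sample = counts.columns[0]
        pairs = synthdata.simulate_reads(library, counts, small_config, sample)
        for name, r1, r2 in pairs[:500]:
            src = library[name.split(":")[1]].sequence
            assert r1 in src
            assert refindex.reverse_complement(r2) in src

    def test_zero_counts_give_empty_valid_fastq(self, small_config, small_library, tmp_path):
        library, _ = small_library
        counts, _ = synthdata.simulate_counts(library, small_config)
        zero = counts.copy()
        zero.iloc[:, :] = 0
        sample = counts.columns[0]
        pairs = synthdata.simulate_reads(library, zero, small_config, sample)
        assert pairs == []
        r1, r2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        synthdata.write_paired_fastq(pairs, r1, r2)
        assert r1.read_text() == "" and r2.read_text() == ""

    def test_fastq_round_trip(self, small_config, small_library, tmp_path):
        from hervex.quant import read_fastq

        library, _ = small_library
        counts, _ = synthdata.simulate_counts(library, small_config)
        sample = counts.columns[0]
        pairs = synthdata.simulate_reads(library, counts, small_config, sample)
        r1, r2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        synthdata.write_paired_fastq(pairs, r1, r2)
        back = list(read_fastq(r1))
        assert len(back) == len(pairs)
        assert back[0][1] == pairs[0][1]


class TestDroplets:
    def test_zero_copies_zero_positives(self):
        assay = synthdata.simulate_droplets(0, 1000, seed=1)
        assert assay.n_positive == 0

    def test_unit_occupancy_positive_fraction(self):
        # Poisson occupancy: at lambda=1 the positive fraction -> 1 - e^-1
        fracs = [
            synthdata.simulate_droplets(5000, 5000, seed=s).n_positive / 5000
            for s in range(30)
        ]
        assert abs(np.mean(fracs) - (1 - np.exp(-1))) < 0.01

    def test_saturation(self):
        assay = synthdata.simulate_droplets(10_000_000, 500, seed=2)
        assert assay.n_positive == 500

    @pytest.mark.parametrize("copies,droplets", [(-1, 100), (100, 0)])
    def test_invalid_inputs_rejected(self, copies, droplets):
        with pytest.raises(ValueError):
            synthdata.simulate_droplets(copies, droplets)
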