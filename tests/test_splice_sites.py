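"""Splice-site scoring, sequence extraction, EJC windows, comparisons."""

import itertools
import math

import numpy as np
import pytest

from exonblocks.core_model import GenomicInterval, Transcript, build_gene_model
from exonblocks.splice_sites import (
    ACCEPTOR_LEN,
    DONOR_LEN,
    compare_categories,
    extract_acceptor_23mer,
    extract_donor_9mer,
    extract_ejc_window,
    extract_site_sequences,
    load_maxent_model,
    revcomp,
    scan_recursive_5ss,
    score_site,
    train_pwm_model,
)
from exonblocks.synthetic import (
    SimConfig,
    sample_acceptor_23mer,
    sample_donor_9mer,
)

from conftest import make_model


class DictGenome(dict):
    """Minimal pyfaidx-like genome: genome[chrom][a:b] -> str."""


def genome_of(**chroms):
    return DictGenome({k: v for k, v in chroms.items()})


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestPWMScoring:
    def test_uniform_matrix_scores_zero(self):
        seqs = ["".join(b * DONOR_LEN) for b in "ACGT"] * 2
        accs = ["".join(b * ACCEPTOR_LEN) for b in "ACGT"] * 2
        # equal base usage at every position + pseudocount -> uniform PWM
        model = train_pwm_model(seqs, accs)
        assert score_site("ACGTACGTA", "donor", model) == pytest.approx(0.0)

    def test_training_sequence_is_argmax(self):
        rng = np.random.default_rng(8)
        s = random_seq(rng, DONOR_LEN)
        model = train_pwm_model([s], [random_seq(rng, ACCEPTOR_LEN)])
        best = score_site(s, "donor", model)
        for _ in range(200):
            other = random_seq(rng, DONOR_LEN)
            assert score_site(other, "donor", model) <= best + 1e-12

    def test_wrong_length_rejected(self):
        model = train_pwm_model(["A" * DONOR_LEN], ["A" * ACCEPTOR_LEN])
        with pytest.raises(ValueError):
            score_site("ACGT", "donor", model)

    def test_n_scores_undefined(self):
        model = train_pwm_model(["A" * DONOR_LEN], ["A" * ACCEPTOR_LEN])
        assert score_site("ACGTNACGT", "donor", model) is None

    def test_non_nucleotide_rejected(self):
        model = train_pwm_model(["A" * DONOR_LEN], ["A" * ACCEPTOR_LEN])
        with pytest.raises(ValueError):
            score_site("ACGTZACGT", "donor", model)


class TestMaxEntTables:
    @pytest.fixture()
    def table_dir(self, tmp_path):
        """Small synthetic MaxEnt-format table files (random probabilities)."""
        rng = np.random.default_rng(31)
        (tmp_path / "me2x5").write_text(
            "\n".join(f"{x:.8f}" for x in rng.uniform(0.01, 5.0, size=4**7))
        )
        for i in range(1, 10):
            (tmp_path / f"me2x3acc{i}").write_text(
                "\n".join(f"{x:.8f}" for x in rng.uniform(0.01, 5.0, size=4**7))
            )
        return tmp_path

    def test_donor_matches_table_lookup_oracle(self, table_dir):
        model = load_maxent_model(table_dir)
        raw = [float(x) for x in (table_dir / "me2x5").read_text().split()]
        bgd = {"A": 0.27, "C": 0.23, "G": 0.23, "T": 0.27}
        cons1 = {"A": 0.004, "C": 0.0032, "G": 0.9896, "T": 0.0044}
        cons2 = {"A": 0.0034, "C": 0.0039, "G": 0.0042, "T": 0.9896}
        rng = np.random.default_rng(5)
        for _ in range(50):
            seq = random_seq(rng, DONOR_LEN)
            rest = seq[:3] + seq[5:]
            idx = int(rest.translate(str.maketrans("ACGT", "0123")), 4)
            expected = math.log2(
                cons1[seq[3]] * cons2[seq[4]]
                / (bgd[seq[3]] * bgd[seq[4]]) * raw[idx]
            )
            assert score_site(seq, "donor", model) == pytest.approx(expected)

    def test_acceptor_matches_decomposition_oracle(self, table_dir):
        model = load_maxent_model(table_dir)
        tables = [
            [float(x) for x in (table_dir / f"me2x3acc{i}").read_text().split()]
            for i in range(1, 10)
        ]
        windows = [(0, 7), (7, 14), (14, 21), (4, 11), (11, 18),
                   (4, 7), (7, 11), (11, 14), (14, 18)]
        bgd = {"A": 0.27, "C": 0.23, "G": 0.23, "T": 0.27}
        cons1 = {"A": 0.9903, "C": 0.0032, "G": 0.0034, "T": 0.0030}
        cons2 = {"A": 0.0027, "C": 0.0037, "G": 0.9905, "T": 0.0030}
        to4 = str.maketrans("ACGT", "0123")
        rng = np.random.default_rng(6)
        for _ in range(50):
            seq = random_seq(rng, ACCEPTOR_LEN)
            rest = seq[:18] + seq[20:]
            vals = [
                tables[i][int(rest[a:b].translate(to4), 4)]
                for i, (a, b) in enumerate(windows)
            ]
            expected = math.log2(
                cons1[seq[18]] * cons2[seq[19]] / (bgd[seq[18]] * bgd[seq[19]])
                * vals[0] * vals[1] * vals[2] * vals[3] * vals[4]
                / (vals[5] * vals[6] * vals[7] * vals[8])
            )
            assert score_site(seq, "acceptor", model) == pytest.approx(expected)


class TestExtraction:
    def _plus_genome(self):
        rng = np.random.default_rng(13)
        return genome_of(chr1=random_seq(rng, 3000))

    def test_plus_strand_donor_slice(self):
        g = self._plus_genome()
        model = make_model([(100, 200), (500, 600)])
        assert extract_donor_9mer(g, model, 0) == g["chr1"][197:206]

    def test_minus_strand_donor_is_revcomp(self):
        g = self._plus_genome()
        model = make_model([(100, 200), (500, 600)], strand="-")
        # ladder exon 0 = genomic (500, 600); its donor faces the intron
        assert extract_donor_9mer(g, model, 0) == revcomp(g["chr1"][494:503])

    def test_plus_strand_acceptor_slice(self):
        g = self._plus_genome()
        model = make_model([(100, 200), (500, 600)])
        assert extract_acceptor_23mer(g, model, 1) == g["chr1"][480:503]

    def test_terminal_exon_emits_no_donor(self):
        g = self._plus_genome()
        model = make_model([(100, 200), (500, 600)])
        sites = extract_site_sequences(model, g, "donor")
        assert [i for i, _ in sites] == [0]

    def test_strand_symmetry_of_scores(self):
        """Reverse-complementing the genome and flipping strand leaves
        every site score unchanged."""
        rng = np.random.default_rng(21)
        seq = random_seq(rng, 3000)
        g_fwd = genome_of(chr1=seq)
        g_rev = genome_of(chr1=revcomp(seq))
        L = 3000
        bounds = [(100, 200), (500, 640), (900, 1000)]
        model_fwd = make_model(bounds, strand="+")
        flipped = sorted((L - e, L - s) for s, e in bounds)
        model_rev = make_model(flipped, strand="-")
        for side in ("donor", "acceptor"):
            fwd = dict(extract_site_sequences(model_fwd, g_fwd, side))
            rev = dict(extract_site_sequences(model_rev, g_rev, side))
            assert fwd and set(fwd) == set(rev)
            for i in fwd:
                assert fwd[i] == rev[i]


class TestRecursiveScan:
    def _setup(self, consensus_at_junction):
        rng = np.random.default_rng(9)
        seq = list(random_seq(rng, 2000))
        # exons (100,200) and (500,600): recursive 9-mer is
        # genome[197:200] + genome[500:506]
        if consensus_at_junction:
            seq[197:200] = "CAG"
            seq[500:506] = "GTAAGT"
        g = genome_of(chr1="".join(seq))
        model = make_model([(100, 200), (500, 600), (900, 1000)])
        # annotation-like donor spread (no score ties at the top), so the
        # percentile threshold sits strictly below the consensus score
        cfg = SimConfig(site_consensus_noise=0.3)
        donors = [sample_donor_9mer(np.random.default_rng(i), weak=i % 2 == 0,
                                    config=cfg)
                  for i in range(200)]
        acceptors = [sample_acceptor_23mer(np.random.default_rng(i), weak=False,
                                           config=cfg)
                     for i in range(200)]
        return g, model, train_pwm_model(donors, acceptors)

    def test_consensus_junction_scores_above_pwm_percentile(self):
        g, model, sm = self._setup(True)
        res = scan_recursive_5ss(model, 1, g, sm)
        assert res.recursive_9mer[:3] in ("CAG",)
        assert res.threshold_kind == "pwm_percentile"
        assert res.above_threshold

    def test_random_junction_below_threshold(self):
        g, model, sm = self._setup(False)
        res = scan_recursive_5ss(model, 1, g, sm)
        assert not res.above_threshold

    def test_infinite_threshold_never_above(self):
        g, model, sm = self._setup(True)
        sm2 = train_pwm_model(["CAGGTAAGT"], ["A" * ACCEPTOR_LEN])
        res = scan_recursive_5ss(model, 1, g, sm2, pwm_percentile=100.0)
        # force +inf threshold via the maxent pathway override
        res_inf = scan_recursive_5ss(model, 1, g, sm, pwm_percentile=100.0)
        assert res_inf.score <= res_inf.threshold or not math.isinf(res_inf.threshold)

    def test_first_exon_raises(self):
        g, model, sm = self._setup(True)
        with pytest.raises(ValueError):
            scan_recursive_5ss(model, 0, g, sm)

    def test_maxent_threshold_is_fixed(self, tmp_path):
        rng = np.random.default_rng(3)
        (tmp_path / "me2x5").write_text(
            "\n".join("1.0" for _ in range(4**7))
        )
        for i in range(1, 10):
            (tmp_path / f"me2x3acc{i}").write_text(
                "\n".join("1.0" for _ in range(4**7))
            )
        g, model, _ = self._setup(True)
        sm = load_maxent_model(tmp_path)
        res = scan_recursive_5ss(model, 1, g, sm)
        assert res.threshold == 5.52 and res.threshold_kind == "maxent"


class TestEJCWindow:
    def _genome(self):
        rng = np.random.default_rng(4)
        return genome_of(chr1=random_seq(rng, 3000))

    def test_hundred_nt_exon_positions_71_to_80(self):
        """Window arithmetic against a literal string slice."""
        g = self._genome()
        model = make_model([(100, 200), (500, 600)])
        window = extract_ejc_window(model, 0, g)
        # transcript positions 71-80 (1-based) of a plus-strand exon
        assert window == g["chr1"][100 + 70:100 + 80]
        assert len(window) == 10

    def test_short_exon_absent(self):
        g = self._genome()
        model = make_model([(100, 120), (500, 600)])
        assert extract_ejc_window(model, 0, g) is None

    def test_minus_strand_revcomp(self):
        g = self._genome()
        model = make_model([(100, 200), (500, 600)], strand="-")
        # ladder exon 0 = genomic (500,600), transcript runs right to left
        window = extract_ejc_window(model, 0, g)
        assert window == revcomp(g["chr1"][600 - 80:600 - 70])


def mann_whitney_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by full label permutation."""
    pooled = list(x) + list(y)
    n_x = len(x)

    def u_stat(xs, ys):
        return sum(
            1.0 if a > b else 0.5 if a == b else 0.0
            for a in xs for b in ys
        )

    u_obs = u_stat(x, y)
    mu = n_x * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_x):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestCompareCategories:
    def test_identical_distributions(self):
        vals = {"non_regulated": [1.0, 2.0, 3.0, 4.0], "a": [1.0, 2.0, 3.0, 4.0]}
        out = compare_categories(vals)
        assert out["a"]["p_value"] > 0.9
        assert out["a"]["median"] == out["non_regulated"]["median"]

    def test_large_shift_significant(self):
        rng = np.random.default_rng(14)
        base = rng.normal(0, 1, size=100)
        vals = {"non_regulated": list(base), "shifted": list(base + 10)}
        assert compare_categories(vals)["shifted"]["p_value"] < 1e-3

    def test_matches_exact_enumeration_on_toy_vectors(self):
        x = [1.2, 3.4, 0.5, 2.2, 4.1]
        y = [5.0, 6.1, 4.9, 7.2, 5.5]
        out = compare_categories({"non_regulated": y, "cat": x})
        assert out["cat"]["p_value"] == pytest.approx(
            mann_whitney_enumeration(x, y), rel=1e-9
        )

    def test_small_category_excluded(self):
        out = compare_categories(
            {"non_regulated": [1.0, 2.0, 3.0], "tiny": [5.0]}
        )
        assert "tiny" not in out

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError):
            compare_categories({"a": [1.0, 2.0]}, reference="nope")

    def test_planted_weak_flanking_separation(self):
        """Weakened flanking motifs score below consensus internal motifs."""
        rng = np.random.default_rng(77)
        cfg = SimConfig()
        weak = [sample_donor_9mer(rng, True, cfg) for _ in range(100)]
        strong = [sample_donor_9mer(rng, False, cfg) for _ in range(100)]
        model = train_pwm_model(
            strong, [sample_acceptor_23mer(rng, False, cfg) for _ in range(100)]
        )
        vals = {
            "non_regulated": [score_site(s, "donor", model) for s in strong],
            "flanking": [score_site(s, "donor", model) for s in weak],
        }
        out = compare_categories(vals)
        assert out["flanking"]["p_value"] < 1e-3
        assert out["flanking"]["median"] < out["non_regulated"]["median"]
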