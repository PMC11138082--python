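"""Reading, validation, and allele harmonization of summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tsmr import SummaryStats, harmonize, read_summary_stats, write_summary_stats
from tsmr.exceptions import ConfigurationError, EmptyInputError

from conftest import stats_frame


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReader:
    def test_reads_tsv_with_canonical_headers(self, tmp_path):
        p = _write(
            tmp_path,
            "t.tsv",
            "snp\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"
            "rs1\tA\tG\t0.3\t0.1\t0.02\t1e-9\t5000\n"
            "rs2\tT\tC\t0.4\t-0.2\t0.05\t0.2\t5000\n"
            "rs3\tA\tC\t0.2\t0.05\t0.01\t0.04\t5000\n",
        )
        s = read_summary_stats(p, trait_id="t")
        assert len(s) == 3 and s.n_dropped_rows == 0
        assert s.snp_ids == ["rs1", "rs2", "rs3"]

    def test_nonpositive_se_rows_dropped_and_counted(self, tmp_path):
        p = _write(
            tmp_path,
            "t.tsv",
            "snp\teffect_allele\tother_allele\tbeta\tse\tpval\n"
            "rs1\tA\tG\t0.1\t0.0\t1e-9\n"
            "rs2\tT\tC\t0.2\t0.05\t0.2\n",
        )
        s = read_summary_stats(p)
        assert len(s) == 1 and s.n_dropped_rows == 1
        assert s.snp_ids == ["rs2"]

    def test_csv_with_column_map_matches_tsv_read(self, tmp_path):
        """The same content read through a remapped comma-delimited file must
        yield identical records."""
        tsv = _write(
            tmp_path,
            "a.tsv",
            "snp\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"
            "rs1\tA\tG\t0.3\t0.1\t0.02\t1e-9\t100\n"
            "rs2\tT\tC\t0.4\t-0.2\t0.05\t0.2\t100\n",
        )
        csv = _write(
            tmp_path,
            "b.csv",
            "SNP,EA,OA,FREQ,BETA,SE,P,N\n"
            "rs1,A,G,0.3,0.1,0.02,1e-9,100\n"
            "rs2,T,C,0.4,-0.2,0.05,0.2,100\n",
        )
        s1 = read_summary_stats(tsv, trait_id="x")
        s2 = read_summary_stats(
            csv,
            trait_id="x",
            delimiter=",",
            column_map={
                "snp": "SNP", "effect_allele": "EA", "other_allele": "OA",
                "eaf": "FREQ", "beta": "BETA", "se": "SE", "pval": "P", "n": "N",
            },
        )
        pd.testing.assert_frame_equal(s1.data, s2.data)

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        p = _write(tmp_path, "t.tsv", "snp\tbeta\tse\tpval\nrs1\t0.1\t0.02\t0.5\n")
        with pytest.raises(ConfigurationError):
            read_summary_stats(p)

    def test_zero_valid_rows_is_empty_input_error(self, tmp_path):
        p = _write(
            tmp_path,
            "t.tsv",
            "snp\teffect_allele\tother_allele\tbeta\tse\tpval\n"
            "rs1\tA\tA\t0.1\t0.02\t0.5\n",
        )
        with pytest.raises(EmptyInputError):
            read_summary_stats(p)

    def test_roundtrip(self, tmp_path):
        s = SummaryStats(
            "t", stats_frame([("rs1", "A", "G", 0.3, 0.1, 0.02, 1e-9)])
        )
        write_summary_stats(s, tmp_path / "out.tsv")
        back = read_summary_stats(tmp_path / "out.tsv", trait_id="t")
        pd.testing.assert_frame_equal(s.data, back.data)


class TestValidation:
    @pytest.mark.parametrize(
        "row",
        [
            ("rs1", "A", "G", 0.3, 0.1, -0.01, 0.5),  # negative se
            ("rs1", "A", "G", 0.3, 0.1, 0.02, 0.0),  # p = 0
            ("rs1", "A", "G", 0.3, 0.1, 0.02, 1.5),  # p > 1
            ("rs1", "A", "A", 0.3, 0.1, 0.02, 0.5),  # identical alleles
            ("rs1", "Z", "G", 0.3, 0.1, 0.02, 0.5),  # bad allele letter
        ],
    )
    def test_invariants_enforced_by_constructor(self, row):
        with pytest.raises(ConfigurationError):
            SummaryStats("t", stats_frame([row]))

    def test_duplicate_snp_rejected(self):
        rows = [
            ("rs1", "A", "G", 0.3, 0.1, 0.02, 0.5),
            ("rs1", "T", "C", 0.3, 0.1, 0.02, 0.5),
        ]
        with pytest.raises(ConfigurationError):
            SummaryStats("t", stats_frame(rows))


class TestHarmonize:
    def exposure(self):
        return SummaryStats(
            "exp",
            stats_frame(
                [
                    ("rs1", "A", "G", 0.3, 0.10, 0.02, 1e-9),
                    ("rs2", "T", "C", 0.4, 0.20, 0.02, 1e-9),
                ]
            ),
        )

    def test_allele_swap_flips_beta_sign(self):
        outcome = SummaryStats(
            "out",
            stats_frame(
                [
                    ("rs1", "G", "A", 0.7, 0.05, 0.01, 0.1),
                    ("rs2", "T", "C", 0.4, 0.07, 0.01, 0.1),
                ]
            ),
        )
        h = harmonize(self.exposure(), outcome)
        assert h.k == 2
        np.testing.assert_allclose(h.beta_Y, [-0.05, 0.07])

    def test_strand_complement_recognized(self):
        # (T, C) on the other strand reads (A, G): same orientation as rs1
        outcome = SummaryStats(
            "out",
            stats_frame(
                [
                    ("rs1", "T", "C", 0.3, 0.05, 0.01, 0.1),
                    ("rs2", "T", "C", 0.4, 0.07, 0.01, 0.1),
                ]
            ),
        )
        h = harmonize(self.exposure(), outcome)
        np.testing.assert_allclose(h.beta_Y, [0.05, 0.07])

    def test_allele_mismatch_dropped_with_reason(self):
        outcome = SummaryStats(
            "out",
            stats_frame(
                [
                    ("rs1", "A", "C", 0.3, 0.05, 0.01, 0.1),
                    ("rs2", "T", "C", 0.4, 0.07, 0.01, 0.1),
                ]
            ),
        )
        h = harmonize(self.exposure(), outcome)
        assert h.k == 1
        assert ("rs1", "allele mismatch") in h.dropped

    def palindromic_pair(self, eaf_exp, eaf_out):
        exp = SummaryStats(
            "exp", stats_frame([("rs9", "A", "T", eaf_exp, 0.10, 0.02, 1e-9)])
        )
        out = SummaryStats(
            "out", stats_frame([("rs9", "A", "T", eaf_out, 0.05, 0.01, 0.1)])
        )
        return exp, out

    def test_palindromic_dropped_by_default(self):
        exp, out = self.palindromic_pair(0.10, 0.12)
        with pytest.raises(EmptyInputError):
            harmonize(exp, out)  # the only shared SNP is dropped

    def test_palindromic_inferred_by_concordant_eaf(self):
        exp, out = self.palindromic_pair(0.10, 0.12)
        h = harmonize(exp, out, palindrome_policy="infer_by_eaf", eaf_window=0.08)
        assert h.k == 1
        np.testing.assert_allclose(h.beta_Y, [0.05])  # same orientation retained

    def test_palindromic_discordant_eaf_flips(self):
        exp, out = self.palindromic_pair(0.10, 0.88)
        h = harmonize(exp, out, palindrome_policy="infer_by_eaf")
        np.testing.assert_allclose(h.beta_Y, [-0.05])

    def test_palindromic_ambiguous_eaf_dropped(self):
        exp, out = self.palindromic_pair(0.47, 0.10)
        with pytest.raises(EmptyInputError):
            harmonize(exp, out, palindrome_policy="infer_by_eaf", eaf_window=0.08)

    def test_empty_intersection_errors(self):
        out = SummaryStats(
            "out", stats_frame([("rs99", "A", "G", 0.3, 0.05, 0.01, 0.1)])
        )
        with pytest.raises(EmptyInputError):
            harmonize(self.exposure(), out)


class TestHarmonizeProperties:
    """Structural invariants of harmonization on randomized inputs."""

    @staticmethod
    def _random_pair(seed):
        rng = np.random.default_rng(seed)
        k = 12
        pairs = [("A", "G"), ("T", "C"), ("A", "C"), ("T", "G")]
        rows_e, rows_o = [], []
        for i in range(k):
            ea, oa = pairs[rng.integers(len(pairs))]
            eaf = float(rng.uniform(0.05, 0.95))
            be, bo = rng.normal(0, 0.1, 2)
            rows_e.append((f"rs{i}", ea, oa, eaf, be, 0.02, 0.5))
            if rng.random() < 0.5:  # swap orientation in the outcome file
                rows_o.append((f"rs{i}", oa, ea, 1 - eaf, -bo, 0.02, 0.5))
            else:
                rows_o.append((f"rs{i}", ea, oa, eaf, bo, 0.02, 0.5))
        return (
            SummaryStats("exp", stats_frame(rows_e)),
            SummaryStats("out", stats_frame(rows_o)),
        )

    @given(st.integers(0, 500))
    def test_idempotent_and_accounting(self, seed):
        exp, out = self._random_pair(seed)
        h = harmonize(exp, out)
        assert h.k + len(h.dropped) == 12
        # rebuild SummaryStats from the harmonized arrays: re-harmonizing an
        # already-aligned pair must change nothing
        ref = exp.data.set_index("snp").loc[list(h.snp_ids)]
        aligned = SummaryStats(
            "out",
            stats_frame(
                [
                    (s, ref.at[s, "effect_allele"], ref.at[s, "other_allele"],
                     ref.at[s, "eaf"], h.beta_Y[i], h.se_Y[i], 0.5)
                    for i, s in enumerate(h.snp_ids)
                ]
            ),
        )
        h2 = harmonize(exp.subset(h.snp_ids), aligned)
        np.testing.assert_array_equal(h2.beta_Y, h.beta_Y)
        np.testing.assert_array_equal(h2.beta_X, h.beta_X)

    @given(st.integers(0, 500))
    def test_global_outcome_flip_is_invisible(self, seed):
        exp, out = self._random_pair(seed)
        flipped = out.data.copy()
        flipped[["effect_allele", "other_allele"]] = flipped[
            ["other_allele", "effect_allele"]
        ].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        h1 = harmonize(exp, out)
        h2 = harmonize(exp, SummaryStats("out", flipped))
        np.testing.assert_allclose(h1.beta_Y, h2.beta_Y)
        np.testing.assert_array_equal(h1.snp_ids, h2.snp_ids)
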