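import numpy as np
import pandas as pd
import pytest

from rohscan.genotypes import (
    GenotypeDataset,
    Pedigree,
    PhenotypeTable,
    heterozygosity_percent,
    impute_mode,
    qc_filter,
    read_plink,
    write_plink,
)
from conftest import random_dataset


def _write_hand_fixture(tmp_path):
    """3 samples x 4 SNPs with known dosages of the lexicographically
    smaller allele (A < C, G < T)."""
    (tmp_path / "toy.map").write_text(
        "1\tm1\t0\t100\n1\tm2\t0\t200\n2\tm3\t0\t150\n2\tm4\t0\t250\n"
    )
    (tmp_path / "toy.ped").write_text(
        "f1 s1 0 0 1 -9 A A A C G G T T\n"
        "f2 s2 0 0 2 -9 A C C C G T 0 0\n"
        "f3 s3 0 0 1 -9 C C A A T T G T\n"
    )
    expected = np.array(
        [[2, 1, 2, 0],
         [1, 0, 1, -1],
         [0, 2, 0, 1]],
        dtype=np.int8,
    )
    return expected


class TestPlinkIO:
    def test_hand_written_text_fixture(self, tmp_path):
        expected = _write_hand_fixture(tmp_path)
        gd = read_plink(tmp_path / "toy", dialect="text")
        assert gd.samples == ["s1", "s2", "s3"]
        np.testing.assert_array_equal(gd.calls, expected)
        assert list(gd.markers["position_bp"]) == [100, 200, 150, 250]

    @pytest.mark.parametrize("dialect", ["text", "binary"])
    @pytest.mark.parametrize("missing_rate", [0.0, 0.15])
    def test_round_trip(self, tmp_path, dialect, missing_rate):
        rng = np.random.default_rng(3)
        gd = random_dataset(rng, n_samples=7, markers_per_chrom=(11, 5, 9),
                            missing_rate=missing_rate)
        write_plink(gd, tmp_path / "rt", dialect=dialect)
        back = read_plink(tmp_path / "rt", dialect=dialect)
        assert back.samples == gd.samples
        np.testing.assert_array_equal(back.calls, gd.calls)
        pd.testing.assert_frame_equal(
            back.markers.astype({"position_bp": int}),
            gd.markers.astype({"chromosome": str, "position_bp": int}),
        )

    def test_truncated_bed_errors(self, tmp_path):
        rng = np.random.default_rng(4)
        gd = random_dataset(rng, n_samples=6, markers_per_chrom=(8,))
        write_plink(gd, tmp_path / "tr", dialect="binary")
        raw = (tmp_path / "tr.bed").read_bytes()
        (tmp_path / "tr.bed").write_bytes(raw[:-3])
        with pytest.raises(ValueError, match="bytes"):
            read_plink(tmp_path / "tr", dialect="binary")

    def test_bad_magic_errors(self, tmp_path):
        rng = np.random.default_rng(5)
        gd = random_dataset(rng, n_samples=4, markers_per_chrom=(6,))
        write_plink(gd, tmp_path / "bm", dialect="binary")
        raw = (tmp_path / "bm.bed").read_bytes()
        (tmp_path / "bm.bed").write_bytes(b"\x00\x00" + raw[2:])
        with pytest.raises(ValueError, match="magic"):
            read_plink(tmp_path / "bm", dialect="binary")


class TestQCFilter:
    def _dataset_with_call_rates(self):
        # 50 markers; sample 0 complete, sample 1 at 96%, sample 2 at 94%
        markers = pd.DataFrame(
            {"marker_id": [f"m{j}" for j in range(50)],
             "chromosome": ["1"] * 25 + ["19"] * 25,
             "position_bp": list(range(100, 100 + 25 * 10, 10)) * 2}
        )
        calls = np.ones((3, 50), dtype=np.int8)
        calls[1, :2] = -1   # 48/50 = 0.96
        calls[2, :3] = -1   # 47/50 = 0.94
        return GenotypeDataset(["a", "b", "c"], markers, calls)

    def test_individual_call_rate_threshold(self):
        gd = self._dataset_with_call_rates()
        out = qc_filter(gd, min_ind_call_rate=0.95, min_snp_call_rate=0.0)
        assert out.samples == ["a", "b"]

    def test_autosome_restriction(self):
        gd = self._dataset_with_call_rates()
        out = qc_filter(gd, 0.0, 0.0, autosomes={str(c) for c in range(1, 19)})
        assert set(out.markers["chromosome"]) == {"1"}

    def test_complete_dataset_unchanged(self):
        rng = np.random.default_rng(6)
        gd = random_dataset(rng, missing_rate=0.0)
        out = qc_filter(gd)
        np.testing.assert_array_equal(out.calls, gd.calls)
        assert out.samples == gd.samples

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        gd = random_dataset(rng, n_samples=20, markers_per_chrom=(30,),
                            missing_rate=0.04)
        once = qc_filter(gd)
        twice = qc_filter(once)
        assert twice.samples == once.samples
        np.testing.assert_array_equal(twice.calls, once.calls)

    def test_empty_result_errors(self):
        gd = self._dataset_with_call_rates()
        with pytest.raises(ValueError, match="review thresholds"):
            qc_filter(gd, min_ind_call_rate=1.0, min_snp_call_rate=0.0)


class TestImputeMode:
    def _one_marker(self, calls):
        markers = pd.DataFrame(
            {"marker_id": ["m"], "chromosome": ["1"], "position_bp": [100]}
        )
        return GenotypeDataset([f"s{i}" for i in range(len(calls))], markers,
                               np.array(calls, dtype=np.int8).reshape(-1, 1))

    def test_identity_when_complete(self):
        gd = self._one_marker([0, 1, 2])
        np.testing.assert_array_equal(impute_mode(gd).calls, gd.calls)

    def test_mode_fill(self):
        gd = self._one_marker([0, 0, 2, -1])
        assert impute_mode(gd).calls[3, 0] == 0

    def test_tie_breaks_to_lower_dosage(self):
        gd = self._one_marker([0, 2, -1])
        assert impute_mode(gd).calls[2, 0] == 0

    def test_all_missing_marker_errors(self):
        gd = self._one_marker([-1, -1])
        with pytest.raises(ValueError, match="all calls missing"):
            impute_mode(gd)


class TestHeterozygosity:
    def test_extremes_and_direct_count(self):
        rng = np.random.default_rng(8)
        gd = random_dataset(rng, n_samples=3, markers_per_chrom=(20,))
        gd.calls[0, :] = 1
        gd.calls[1, :] = 2
        gd.calls[2, :] = 0
        gd.calls[2, :7] = 1
        het = heterozygosity_percent(gd)
        assert het[0] == 100.0
        assert het[1] == 0.0
        assert het[2] == pytest.approx(100.0 * 7 / 20)

    def test_chip_scale_count(self):
        # one sow on a 57,450-marker panel with 20,000 heterozygous calls
        m = 57_450
        markers = pd.DataFrame(
            {"marker_id": [f"m{j}" for j in range(m)], "chromosome": "1",
             "position_bp": np.arange(1, m + 1)}
        )
        calls = np.zeros((1, m), dtype=np.int8)
        calls[0, :20_000] = 1
        gd = GenotypeDataset(["sow"], markers, calls)
        assert heterozygosity_percent(gd)[0] == pytest.approx(34.81288, abs=1e-5)

    def test_invariant_to_marker_order_and_allele_swap(self):
        rng = np.random.default_rng(9)
        gd = random_dataset(rng, n_samples=5, markers_per_chrom=(15, 15))
        het = heterozygosity_percent(gd)
        swapped = GenotypeDataset(gd.samples, gd.markers, (2 - gd.calls).astype(np.int8))
        np.testing.assert_allclose(heterozygosity_percent(swapped), het)
        perm = rng.permutation(gd.n_markers)
        markers = gd.markers.iloc[perm].reset_index(drop=True)
        # rebuild a consistent map ordering (positions must increase per chrom)
        reordered = GenotypeDataset(
            gd.samples,
            markers.sort_values(["chromosome", "position_bp"]).reset_index(drop=True),
            gd.calls[:, perm][:, np.argsort(
                markers.sort_values(["chromosome", "position_bp"]).index)],
        )
        np.testing.assert_allclose(heterozygosity_percent(reordered), het)

    def test_missing_calls_rejected(self):
        rng = np.random.default_rng(10)
        gd = random_dataset(rng, missing_rate=0.2)
        with pytest.raises(ValueError, match="impute"):
            heterozygosity_percent(gd)


class TestPedigree:
    def test_topological_sort_and_founders(self):
        ped = Pedigree([("c", "a", "b"), ("a", None, None), ("b", "0", "0")])
        assert ped.ids.index("c") > ped.ids.index("a")
        assert set(ped.founders()) == {"a", "b"}

    def test_cycle_detection(self):
        with pytest.raises(ValueError, match="cycle"):
            Pedigree([("a", "b", None), ("b", "a", None)])

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValueError, match="not in pedigree"):
            Pedigree([("a", "zz", None)])


class TestPhenotypeTable:
    def test_nba_cannot_exceed_tnb(self):
        df = pd.DataFrame(
            {"sow": ["s"], "parity": [1], "hys": ["h1"], "tnb": [8], "nba": [9]}
        )
        with pytest.raises(ValueError, match="NBA"):
            PhenotypeTable(df)

    def test_parity_classes_validated(self):
        df = pd.DataFrame(
            {"sow": ["s"], "parity": [7], "hys": ["h1"], "tnb": [8], "nba": [8]}
        )
        with pytest.raises(ValueError, match="parity"):
            PhenotypeTable(df)
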