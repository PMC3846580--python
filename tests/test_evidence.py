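import numpy as np
import pandas as pd
import pytest

from dhscreen.evidence import (
    EvidenceRecord,
    TfScoreMatrix,
    TrackElement,
    annotate_evidence,
    build_tf_matrix,
    kmeans_classes,
    load_table1_fixture,
    replay_calls,
    evidence_from_fixture,
    summarize_screen,
)
from dhscreen.intervals import GenomicInterval

TRACK_NAMES = ("conserved", "faire", "h3k4me1", "h3k27ac", "gata1", "nfe2")


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


class TestAnnotateEvidence:
    def test_fixture_like_pattern(self):
        # evidence pattern of an upstream candidate: no conservation, FAIRE
        # positive, both histone marks target-specific, GATA-1 only
        site = iv(1_000, 1_400)
        tracks = {
            "faire": [TrackElement(iv(1_100, 1_300))],
            "h3k4me1": [TrackElement(iv(900, 1_500), target_specific=True)],
            "h3k27ac": [TrackElement(iv(1_000, 1_200), target_specific=True)],
            "gata1": [TrackElement(iv(1_200, 1_250))],
            "nfe2": [TrackElement(iv(5_000, 5_400))],  # elsewhere
        }
        rec = annotate_evidence("KLF9-I", site, tracks)
        assert rec == EvidenceRecord(
            site_id="KLF9-I", conserved=False, faire=True,
            h3k4me1="present_target_specific",
            h3k27ac="present_target_specific", gata1=True, nfe2=False,
        )

    def test_no_overlap_all_absent(self):
        site = iv(0, 100)
        tracks = {n: [TrackElement(iv(500, 600))] for n in TRACK_NAMES}
        rec = annotate_evidence("S", site, tracks)
        assert not rec.conserved and not rec.faire
        assert rec.h3k4me1 == "absent" and rec.h3k27ac == "absent"
        assert not rec.gata1 and not rec.nfe2

    def test_absent_track_is_absent_column(self):
        rec = annotate_evidence("S", iv(0, 100), {})
        assert not rec.histone_marked and not rec.tf_occupied

    def test_plain_presence_not_upgraded(self):
        tracks = {"h3k4me1": [TrackElement(iv(0, 50))]}
        rec = annotate_evidence("S", iv(0, 100), tracks)
        assert rec.h3k4me1 == "present"

    def test_brute_force_oracle_500_sites(self):
        rng = np.random.default_rng(0)
        tracks = {}
        for name in TRACK_NAMES:
            els = []
            for _ in range(30):
                s = int(rng.integers(0, 5_000))
                els.append(
                    TrackElement(
                        iv(s, s + int(rng.integers(10, 200))),
                        target_specific=bool(rng.random() < 0.5),
                    )
                )
            tracks[name] = els
        for i in range(500):
            s = int(rng.integers(0, 5_000))
            site = iv(s, s + int(rng.integers(20, 300)))
            rec = annotate_evidence(f"S{i}", site, tracks)
            # oracle: enumerate elements one by one
            for name in TRACK_NAMES:
                hits = [
                    el for el in tracks[name]
                    if site.chrom == el.interval.chrom
                    and site.start < el.interval.end
                    and el.interval.start < site.end
                ]
                if name in ("h3k4me1", "h3k27ac"):
                    if any(el.target_specific for el in hits):
                        expected = "present_target_specific"
                    elif hits:
                        expected = "present"
                    else:
                        expected = "absent"
                    assert getattr(rec, name) == expected
                else:
                    assert getattr(rec, name) == bool(hits)

    def test_monotone_in_track_elements(self):
        rng = np.random.default_rng(1)
        rank = {"absent": 0, "present": 1, "present_target_specific": 2}
        for _ in range(100):
            site = iv(1_000, 1_400)
            tracks = {
                n: [TrackElement(iv(int(rng.integers(0, 2_000)),
                                    int(rng.integers(2_001, 3_000))))]
                for n in TRACK_NAMES
            }
            before = annotate_evidence("S", site, tracks)
            extra = TrackElement(iv(1_100, 1_200), target_specific=True)
            name = str(rng.choice(TRACK_NAMES))
            tracks[name] = list(tracks[name]) + [extra]
            after = annotate_evidence("S", site, tracks)
            for n in TRACK_NAMES:
                if n in ("h3k4me1", "h3k27ac"):
                    assert rank[getattr(after, n)] >= rank[getattr(before, n)]
                else:
                    assert getattr(after, n) >= getattr(before, n)


class TestTfMatrix:
    def test_single_element(self):
        sites = {"S1": iv(0, 100)}
        clusters = [TrackElement(iv(50, 80), name="GATA1", score=800,
                                 cell_type="K562")]
        m = build_tf_matrix(sites, clusters, "K562")
        assert m.frame.loc["S1", "GATA1"] == 800

    def test_max_rule(self):
        sites = {"S1": iv(0, 100)}
        clusters = [
            TrackElement(iv(10, 20), name="TAL1", score=300, cell_type="K562"),
            TrackElement(iv(30, 40), name="TAL1", score=700, cell_type="K562"),
        ]
        m = build_tf_matrix(sites, clusters, "K562")
        assert m.frame.loc["S1", "TAL1"] == 700

    def test_sum_aggregate_option(self):
        sites = {"S1": iv(0, 100)}
        clusters = [
            TrackElement(iv(10, 20), name="TAL1", score=300, cell_type="K562"),
            TrackElement(iv(30, 40), name="TAL1", score=700, cell_type="K562"),
        ]
        m = build_tf_matrix(sites, clusters, "K562", aggregate="sum")
        assert m.frame.loc["S1", "TAL1"] == 1000

    def test_cell_type_filter(self):
        sites = {"S1": iv(0, 100)}
        clusters = [TrackElement(iv(0, 100), name="SP1", score=500,
                                 cell_type="HeLa")]
        m = build_tf_matrix(sites, clusters, "K562")
        assert m.frame.size == 0 or (m.frame.to_numpy() == 0).all()

    def test_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        sites = {}
        for i in range(30):
            s = int(rng.integers(0, 3_000))
            sites[f"S{i}"] = iv(s, s + int(rng.integers(50, 400)))
        tfs = [f"TF{j}" for j in range(8)]
        clusters = [
            TrackElement(
                iv(int(s0 := rng.integers(0, 3_000)), int(s0) + int(rng.integers(10, 300))),
                name=str(rng.choice(tfs)),
                score=float(rng.integers(0, 1001)),
                cell_type="K562",
            )
            for _ in range(120)
        ]
        m = build_tf_matrix(sites, clusters, "K562").frame
        for sid, siv in sites.items():  # brute-force double loop
            for tf in m.columns:
                best = 0.0
                for el in clusters:
                    if (
                        el.name == tf
                        and siv.start < el.interval.end
                        and el.interval.start < siv.end
                    ):
                        best = max(best, el.score)
                assert m.loc[sid, tf] == best


class TestKmeans:
    def _matrix(self, data, index=None):
        frame = pd.DataFrame(
            np.asarray(data, dtype=float),
            index=index or [f"S{i}" for i in range(len(data))],
        )
        return TfScoreMatrix(frame=frame)

    def test_k1_single_class(self):
        m = kmeans_classes(self._matrix(np.arange(12).reshape(4, 3)), k=1)
        assert set(m.row_classes) == {0}
        assert set(m.col_classes) == {0}

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            kmeans_classes(self._matrix(np.ones((3, 3))), k=4)

    def test_planted_blobs_recovered(self):
        rng = np.random.default_rng(3)
        hi = 900 + rng.normal(0, 5, size=(5, 4))
        lo = 50 + rng.normal(0, 5, size=(5, 4))
        m = kmeans_classes(self._matrix(np.vstack([hi, lo])), k=2, seed=0)
        labels = m.row_classes.to_numpy()
        # canonical labels: cluster 0 has the higher mean
        assert (labels[:5] == 0).all()
        assert (labels[5:] == 1).all()

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(4)
        data = rng.integers(0, 1000, size=(12, 5)).astype(float)
        m1 = kmeans_classes(self._matrix(data), k=3, seed=1)
        perm = rng.permutation(12)
        m2 = kmeans_classes(
            self._matrix(data[perm], index=[f"S{i}" for i in perm]), k=3, seed=1
        )
        for i in range(12):
            assert m1.row_classes[f"S{i}"] == m2.row_classes[f"S{i}"]

    def test_beats_random_partitions(self):
        rng = np.random.default_rng(5)
        data = rng.integers(0, 1000, size=(23, 6)).astype(float)
        m = kmeans_classes(self._matrix(data), k=3, seed=0)

        def wcss(labels):
            tot = 0.0
            for lab in np.unique(labels):
                block = data[labels == lab]
                tot += ((block - block.mean(axis=0)) ** 2).sum()
            return tot

        ours = wcss(m.row_classes.to_numpy())
        for _ in range(100):
            rand = rng.integers(0, 3, size=23)
            if len(np.unique(rand)) < 3:
                continue
            assert ours <= wcss(rand) + 1e-9

    def test_wcss_nonincreasing_in_k(self):
        rng = np.random.default_rng(6)
        data = rng.integers(0, 1000, size=(20, 6)).astype(float)

        def wcss_of(k):
            m = kmeans_classes(self._matrix(data), k=k, seed=0)
            labels = m.row_classes.to_numpy()
            tot = 0.0
            for lab in np.unique(labels):
                block = data[labels == lab]
                tot += ((block - block.mean(axis=0)) ** 2).sum()
            return tot

        values = [wcss_of(k) for k in (1, 2, 3, 4)]
        assert all(a >= b - 1e-6 for a, b in zip(values, values[1:]))


class TestSummarize:
    def test_fixture_summary_counts(self, table1_calls, table1_evidence):
        s = summarize_screen(table1_calls, table1_evidence)
        assert s.n_erythroid_specific == 10
        assert s.n_conserved_specific == 5
        assert s.n_histone_marked_specific == 10
        assert s.n_target_specific_marked_specific == 7
        assert s.n_tf_occupied_specific == 6

    def test_fixture_counts_brute_force(self, table1):
        # independent scan of the raw fixture rows
        spec = table1[
            (table1.klfp_k562 == "Y")
            & (table1.klfp_hela == "-")
            & (table1.klfp_hek293 == "-")
        ]
        assert len(spec) == 10
        assert (spec.cs == "Y").sum() == 5
        assert ((spec.h3k4me1 != "-") | (spec.h3k27ac != "-")).sum() == 10
        assert ((spec.h3k4me1 == "Y*") | (spec.h3k27ac == "Y*")).sum() == 7
        assert ((spec.gata1 == "Y") | (spec.nfe2 == "Y")).sum() == 6

    def test_empty_input(self):
        s = summarize_screen([], [])
        assert s.n_sites == 0 and s.n_erythroid_specific == 0

    def test_id_mismatch_raises(self, table1_calls, table1_evidence):
        with pytest.raises(ValueError):
            summarize_screen(table1_calls, table1_evidence[:-1])

    def test_specific_subset_of_promoter_positive(self, table1_calls):
        promoter_positive = {
            c.site_id for c in table1_calls if c.promoter_enhancer["K562"]
        }
        specific = {
            c.site_id for c in table1_calls if c.erythroid_specific_enhancer
        }
        assert specific <= promoter_positive


class TestFixture:
    def test_23_rows(self, table1):
        assert len(table1) == 23
        assert table1["site_id"].nunique() == 23

    def test_klf1_contributes_five(self, table1):
        klf1 = table1[table1.gene == "KLF1"]
        assert list(klf1.dhs_id) == ["I", "II", "III", "IV", "V"]

    def test_spot_checks(self, table1):
        row = table1.set_index("site_id")
        assert row.loc["KLF17-I", "klfp_hela"] == "Y"
        assert row.loc["KLF11-I", "klfp_hela"] == "Y"
        assert row.loc["KLF3-III", "klfp_hek293"] == "Y"
        assert row.loc["KLF9-I", "cs"] == "-"

    def test_replay_categories(self, table1_calls):
        cat = {c.site_id: c.category for c in table1_calls}
        assert cat["KLF6-I"] == "minP_only"
        assert cat["KLF13-III"] == "promoter_only"
        assert cat["KLF1-II"] == "dual"
        assert cat["KLF1-I"] == "non_enhancer"

    def test_replay_specificity_examples(self, table1_calls):
        spec = {c.site_id: c.erythroid_specific_enhancer for c in table1_calls}
        assert spec["KLF9-I"]
        assert not spec["KLF11-I"]
        assert not spec["KLF3-III"]
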