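"""Discriminative score, representative selection, and the manifest."""

import numpy as np
import pytest

from conftest import make_candidates
from pleuradx.rendering import RenderedCandidateSet, target_encoding
from pleuradx.selection import (ClassCentroids, discriminative_score,
                                fit_centroids, read_manifest,
                                select_representatives, selected_images,
                                variance_select, write_manifest)

KINDS = ("decoder", "gan", "nerv")


def _cands_from_vectors(vectors_by_sample, labels):
    """Candidate sets whose three 'images' are given 1-D vectors."""
    out = []
    for i, (vecs, lab) in enumerate(zip(vectors_by_sample, labels)):
        out.append(RenderedCandidateSet(
            sample_id=f"s{i}", label=lab,
            images={k: np.asarray(v, dtype=float).reshape(1, -1)
                    for k, v in zip(KINDS, vecs)}))
    return out


class TestFitCentroids:
    def test_arithmetic_mean(self):
        cands = _cands_from_vectors(
            [[(0, 0)] * 3, [(2, 2)] * 3, [(5, 5)] * 3],
            ["a", "a", "b"])
        c = fit_centroids(cands)
        assert np.allclose(c.centroids["a"], [1, 1])
        assert np.allclose(c.centroids["b"], [5, 5])

    def test_matches_brute_force_summation(self, rng):
        vecs = [[rng.normal(size=4) for _ in KINDS] for _ in range(5)]
        labels = ["a", "b", "a", "b", "a"]
        cands = _cands_from_vectors(vecs, labels)
        c = fit_centroids(cands)
        for lab in ("a", "b"):
            pool = [np.asarray(v, float) for vs, l in zip(vecs, labels)
                    for v in vs if l == lab]
            assert np.allclose(c.centroids[lab],
                               np.sum(pool, axis=0) / len(pool))

    def test_fit_ids_restrict_and_missing_class_raises(self):
        cands = _cands_from_vectors([[(0, 0)] * 3, [(4, 4)] * 3],
                                    ["a", "b"])
        c = fit_centroids(cands, fit_ids=["s0", "s1"])
        assert np.allclose(c.centroids["a"], [0, 0])
        with pytest.raises(ValueError):
            fit_centroids(cands, fit_ids=["s0"])


class TestDiscriminativeScore:
    def test_ratio_example(self):
        assert discriminative_score([0, 0], [1, 0], [3, 0]) == 3.0

    def test_equidistant_gives_one(self):
        assert discriminative_score([0, 1], [1, 1], [-1, 1]) == 1.0

    def test_coincidence_sentinel(self):
        s = discriminative_score([1, 0], [1, 0], [4, 0])
        assert s == pytest.approx(3.0 / 1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            discriminative_score([0, 0], [1, 0, 0], [3, 0])

    def test_invariance_under_joint_rotation_and_scaling(self, rng):
        for _ in range(20):
            m, cp, cn = rng.normal(size=(3, 6))
            q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
            base = discriminative_score(m, cp, cn)
            rotated = discriminative_score(q @ m, q @ cp, q @ cn)
            scaled = discriminative_score(3.7 * m, 3.7 * cp, 3.7 * cn)
            assert rotated == pytest.approx(base, rel=1e-9)
            assert scaled == pytest.approx(base, rel=1e-9)


class TestSelectRepresentatives:
    def _centroids(self):
        return ClassCentroids(centroids={"a": np.array([0.0, 0.0]),
                                         "b": np.array([10.0, 0.0])})

    def test_engineered_winner(self):
        # decoder sits at own centroid + epsilon; others at the midpoint
        cands = _cands_from_vectors(
            [[(0.1, 0.0), (5.0, 0.0), (5.0, 0.0)]], ["a"])
        rows = select_representatives(cands, self._centroids())
        assert rows[0].selected_method == "decoder"

    def test_tie_breaks_in_fixed_order(self):
        cands = _cands_from_vectors([[(2.0, 1.0)] * 3], ["a"])
        rows = select_representatives(cands, self._centroids())
        assert rows[0].selected_method == "decoder"
        rows = variance_select(cands)
        assert rows[0].selected_method == "decoder"

    def test_matches_brute_force_argmax(self, rng):
        cents = self._centroids()
        for _ in range(15):
            vecs = [rng.normal(size=2) * 5 for _ in KINDS]
            cands = _cands_from_vectors([vecs], ["b"])
            rows = select_representatives(cands, cents)
            scores = [np.linalg.norm(v - cents.centroids["a"])
                      / np.linalg.norm(v - cents.centroids["b"])
                      for v in vecs]
            assert rows[0].selected_method == KINDS[int(np.argmax(scores))]

    def test_min_orientation_flag(self, rng):
        cents = self._centroids()
        vecs = [rng.normal(size=2) * 5 for _ in KINDS]
        cands = _cands_from_vectors([vecs], ["a"])
        hi = select_representatives(cands, cents, orientation="max")[0]
        lo = select_representatives(cands, cents, orientation="min")[0]
        scores = [np.linalg.norm(v - cents.centroids["b"])
                  / np.linalg.norm(v - cents.centroids["a"])
                  for v in vecs]
        assert hi.selected_method == KINDS[int(np.argmax(scores))]
        assert lo.selected_method == KINDS[int(np.argmin(scores))]

    def test_one_row_per_sample_and_missing_candidate(self):
        cands = _cands_from_vectors([[(1, 1)] * 3, [(2, 2)] * 3],
                                    ["a", "b"])
        rows = select_representatives(cands, self._centroids())
        assert [r.index for r in rows] == [0, 1]
        del cands[0].images["gan"]
        with pytest.raises(ValueError):
            select_representatives(cands, self._centroids())

    def test_selection_recovery_from_corruption(self):
        """With one clean renderer and two corrupted toward the rival
        class, DS selection recovers the clean one in >= 90% of cases."""
        rng = np.random.default_rng(42)
        n = 60
        labels = ["pos" if i % 2 == 0 else "neg" for i in range(n)]
        z_for = {"pos": np.array([0.85, 0.15]), "neg": np.array([0.15, 0.85])}
        clean_kind = [KINDS[i % 3] for i in range(n)]

        def corrupt(kind, img, i):
            if kind == clean_kind[i]:
                return img
            rival = "neg" if labels[i] == "pos" else "pos"
            noisy = 0.45 * img + 0.55 * target_encoding(z_for[rival])
            return np.clip(noisy + rng.normal(0, 0.25, img.shape), -1, 1)

        cands = make_candidates([z_for[l] for l in labels], labels,
                                corrupt=corrupt)
        cents = fit_centroids(cands)
        rows = select_representatives(cands, cents)
        recovered = np.mean([r.selected_method == clean_kind[i]
                             for i, r in enumerate(rows)])
        assert recovered >= 0.9


class TestVarianceSelect:
    def test_constant_candidate_excluded(self, rng):
        vecs = [np.zeros(8), rng.normal(size=8), rng.normal(size=8)]
        rows = variance_select(_cands_from_vectors([vecs], ["a"]))
        assert rows[0].selected_method in ("gan", "nerv")

    def test_matches_brute_force_ranking(self, rng):
        for _ in range(10):
            vecs = [rng.normal(scale=rng.uniform(0.1, 3), size=16)
                    for _ in KINDS]
            rows = variance_select(_cands_from_vectors([vecs], ["a"]))
            assert rows[0].selected_method == \
                KINDS[int(np.argmax([np.var(v) for v in vecs]))]


class TestManifest:
    def test_round_trip_bit_exact(self, tmp_path):
        cands = _cands_from_vectors([[(1, 1)] * 3] * 3, ["a", "b", "a"])
        rows = variance_select(cands)
        p1, p2 = tmp_path / "m1.csv", tmp_path / "m2.csv"
        write_manifest(rows, p1)
        loaded = read_manifest(p1)
        assert loaded == rows
        write_manifest(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_header_mismatch_and_bad_rows(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("Index,Method,Label,Path\n0,decoder,a,x.png\n")
        with pytest.raises(ValueError, match="Selected_Method"):
            read_manifest(p)
        p.write_text("Index,Selected_Method,Label,Image_Path\nx,decoder,a,p\n")
        with pytest.raises(ValueError, match="line 2"):
            read_manifest(p)

    def test_parses_reference_style_row(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("Index,Selected_Method,Label,Image_Path\n"
                     "0,decoder,Diseased,out/decoder/Diseased/img_0.png\n")
        row = read_manifest(p)[0]
        assert (row.index, row.selected_method, row.label) == \
            (0, "decoder", "Diseased")

    def test_selected_images_materialization(self):
        cands = _cands_from_vectors([[(i, i), (9, 9), (0, 0)]
                                     for i in range(3)], ["a"] * 3)
        cents = ClassCentroids(centroids={"a": np.array([0.0, 0.0]),
                                          "b": np.array([10.0, 10.0])})
        rows = select_representatives(cands, cents)
        imgs = selected_images(cands, rows)
        assert len(imgs) == 3
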