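"""Sliding-window annotation, local maxima, mean-shift counting."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import imagechain as ic
from imagechain.annotate import lattice_sites, mean_shift
from imagechain.volume import Coordinate, ImageVolume


def brute_force_maxima(data, radius, floor):
    """Exhaustive neighbourhood comparison + plateau deduplication."""
    nz, ny, nx = data.shape
    keep = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = data[z, y, x]
                if v <= floor:
                    continue
                is_max = True
                for dz, dy, dx in itertools.product(
                        range(-radius, radius + 1), repeat=3):
                    tz, ty, tx = z + dz, y + dy, x + dx
                    if 0 <= tz < nz and 0 <= ty < ny and 0 <= tx < nx:
                        if data[tz, ty, tx] > v:
                            is_max = False
                            break
                if is_max:
                    keep.append((x, y, z))
    # deduplicate connected equal-valued plateaus to the lexicographic min
    keep_set = set(keep)
    result = []
    seen = set()
    for pt in sorted(keep):
        if pt in seen:
            continue
        # flood within the plateau
        stack, comp = [pt], set()
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            cx, cy, cz = cur
            for dz, dy, dx in itertools.product((-1, 0, 1), repeat=3):
                nb = (cx + dx, cy + dy, cz + dz)
                if nb in keep_set and nb not in comp \
                        and data[nb[2], nb[1], nb[0]] == \
                        data[cz, cy, cx]:
                    stack.append(nb)
        seen |= comp
        result.append(min(comp))
    return sorted(result)


class TestLocalMaxima:
    def test_single_bright_voxel(self):
        data = np.zeros((5, 9, 9))
        data[2, 4, 6] = 100.0
        out = ic.local_maxima(ImageVolume(data),
                              ic.MaximaSpec(radius=1, floor=1.0))
        assert out == [Coordinate(6, 4, 2)]

    def test_constant_volume_below_floor_is_empty(self):
        vol = ImageVolume(np.full((3, 6, 6), 2.0))
        assert ic.local_maxima(vol, ic.MaximaSpec(floor=5.0)) == []

    def test_plateau_deduplicates_to_lexicographic_min(self):
        data = np.zeros((1, 6, 6))
        data[0, 2:4, 2:4] = 7.0  # 2x2 plateau
        out = ic.local_maxima(ImageVolume(data),
                              ic.MaximaSpec(radius=1, floor=1.0))
        assert out == [Coordinate(2, 2, 0)]

    def test_matches_exhaustive_neighborhood_oracle(self, rng):
        from scipy import ndimage as ndi
        data = ndi.gaussian_filter(rng.uniform(0, 10, (6, 14, 14)), 1.2)
        floor = float(np.median(data))
        out = ic.local_maxima(ImageVolume(data),
                              ic.MaximaSpec(radius=1, floor=floor))
        expected = brute_force_maxima(data, 1, floor)
        assert [c.as_tuple() for c in out] == expected


class TestSlidingAnnotate:
    def test_interval_1_annotates_every_pixel(self, counting_model,
                                              blob_pair):
        _, _, test_v, _ = blob_pair
        sub = ImageVolume(test_v.data[:, :10, :10])
        grid = ic.sliding_annotate(counting_model, sub,
                                   ic.SlidingSpec(1))
        assert len(grid.decisions) == 10 * 10 * sub.nz

    def test_interval_3_lattice_count(self):
        vol = ImageVolume(np.zeros((1, 10, 10)) + 1.0)
        sites = lattice_sites(vol, 3)
        assert len(sites) == 16  # 0,3,6,9 per axis

    def test_restrict_to_yields_exactly_those_sites(self, counting_model,
                                                    blob_pair):
        _, _, test_v, _ = blob_pair
        pts = [Coordinate(5, 5, 5), Coordinate(10, 10, 5),
               Coordinate(20, 20, 10), Coordinate(30, 30, 12),
               Coordinate(40, 40, 12)]
        grid = ic.sliding_annotate(counting_model, test_v, restrict_to=pts)
        assert [c for c, _, _ in grid.decisions] == pts

    def test_restriction_to_full_lattice_equals_no_restriction(
            self, counting_model, blob_pair):
        _, _, test_v, _ = blob_pair
        sub = ImageVolume(test_v.data[10:12, 20:28, 20:28])
        spec = ic.SlidingSpec(1)
        direct = ic.sliding_annotate(counting_model, sub, spec)
        restricted = ic.sliding_annotate(
            counting_model, sub, spec,
            restrict_to=lattice_sites(sub, 1))
        assert direct.decisions == restricted.decisions

    def test_annotation_deterministic(self, counting_model, blob_pair):
        _, _, test_v, _ = blob_pair
        pts = ic.local_maxima(test_v)
        g1 = ic.sliding_annotate(counting_model, test_v, restrict_to=pts)
        g2 = ic.sliding_annotate(counting_model, test_v, restrict_to=pts)
        assert g1.decisions == g2.decisions


class TestMergeCenters:
    def test_two_candidates_in_one_blob_merge(self):
        spec = ic.BlobVolumeSpec(n_blobs=1, seed=2)
        vol, centers = ic.gen_blob_volume(spec)
        c = centers[0]
        cands = [c, Coordinate(c.x + 1, c.y, c.z)]
        n, merged = ic.merge_centers(cands, vol, merge_radius=3.0)
        assert n == 1

    def test_candidates_at_distant_blobs_stay_separate(self):
        vol, centers = ic.gen_blob_volume(
            ic.BlobVolumeSpec(n_blobs=2, min_separation=25.0, seed=3))
        n, merged = ic.merge_centers(centers, vol, merge_radius=3.0)
        assert n == 2

    def test_mean_shift_converges_to_blob_mode(self):
        vol, centers = ic.gen_blob_volume(
            ic.BlobVolumeSpec(n_blobs=1, noise_sigma=0.0, seed=4))
        c = centers[0]
        start = Coordinate(c.x + 2, c.y, c.z)
        converged = mean_shift(vol, start, radius=4.0)
        assert np.linalg.norm(converged - np.array(c.as_tuple())) <= 1.0

    def test_empty_candidates(self, blob_pair):
        _, _, test_v, _ = blob_pair
        assert ic.merge_centers([], test_v, 3.0) == (0, [])


class TestEndToEndCounting:
    def test_blob_count_and_centers_recovered(self, counting_model,
                                              blob_pair):
        """Train on one volume's ROIs, count blobs in a second volume:
        the count must land within 10% of truth and centre matching must
        reach F1 >= 0.9 at 3-voxel tolerance."""
        _, _, test_v, test_c = blob_pair
        maxima = ic.local_maxima(test_v)
        grid = ic.sliding_annotate(counting_model, test_v,
                                   restrict_to=maxima)
        candidates = grid.coordinates_for("pos")
        n, centers = ic.merge_centers(candidates, test_v, merge_radius=3.0)
        truth = np.array([c.as_tuple() for c in test_c], float)
        found = np.array([c.as_tuple() for c in centers], float)
        assert abs(n - len(test_c)) <= 0.1 * len(test_c)
        d = cdist(found, truth)
        precision = (d.min(axis=1) <= 3).mean()
        recall = (d.min(axis=0) <= 3).mean()
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.9


class TestMultilabelAnnotate:
    @pytest.fixture()
    def binary_models(self, tmp_path_factory):
        """One binary model per label over whole-image mean intensity."""
        import tifffile
        root = tmp_path_factory.mktemp("ml")
        rng = np.random.default_rng(0)
        models = {}
        for label, level in (("bright", 200.0), ("mid", 100.0)):
            d = root / label
            for cls, mean in ((label, level), ("absent", 10.0)):
                cdir = d / cls
                cdir.mkdir(parents=True)
                for i in range(6):
                    img = rng.normal(mean, 2.0, (8, 8)).clip(0, 255)
                    tifffile.imwrite(cdir / f"i{i}.tif",
                                     img.astype(np.float32))
            ls = ic.load_labeled_set("directory-tree", d)
            chain = ic.AlgorithmChain(
                f"{label}-chain", [ic.make_extractor("mean-intensity")],
                classifier=ic.ClassifierSpec(kind="knn", k=1))
            models[label] = ic.train_model(chain, ls)
        return models

    def test_image_positive_under_both_models_gets_both_labels(
            self, binary_models):
        # 200 is nearest the positive exemplars of both binary models
        img = ImageVolume(np.full((8, 8), 200.0))
        report = ic.multilabel_annotate(binary_models, [img])
        assert report[0][1] == ["bright", "mid"]

    def test_all_negative_image_still_listed_with_empty_set(
            self, binary_models):
        img = ImageVolume(np.full((8, 8), 10.0))
        report = ic.multilabel_annotate(binary_models, [img])
        assert len(report) == 1
        assert report[0][1] == []

    def test_output_is_union_of_individual_binary_predictions(
            self, binary_models):
        rng = np.random.default_rng(1)
        imgs = [ImageVolume(rng.uniform(0, 250, (8, 8))) for _ in range(5)]
        report = ic.multilabel_annotate(binary_models, imgs)
        for i, img in enumerate(imgs):
            expected = []
            for label in sorted(binary_models):
                model = binary_models[label]
                pred = model.predict_volumes([img])[0]
                if pred == label:
                    expected.append(label)
            assert report[i][1] == expected

    def test_non_binary_model_is_contract_error(self, binary_models,
                                                texture_set):
        three = ic.train_model(
            ic.AlgorithmChain("t", [ic.make_extractor("mean-intensity")],
                              classifier=ic.ClassifierSpec(kind="knn")),
            texture_set)
        three.classes = ["a", "b", "c"]  # force a 3-class model
        with pytest.raises(Exception, match="binary"):
            ic.multilabel_annotate({"x": three},
                                   [ImageVolume(np.ones((8, 8)))])
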