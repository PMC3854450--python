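import numpy as np
import pytest

import imagechain as ic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def texture_set(tmp_path_factory):
    """Easy two-class texture tree, loaded through the directory-tree mode."""
    root = tmp_path_factory.mktemp("textures")
    return ic.gen_texture_set(ic.TextureSetSpec(seed=0), root)


@pytest.fixture(scope="session")
def blob_pair():
    """(train volume, train centers, test volume, test centers)."""
    train_v, train_c = ic.gen_blob_volume(ic.BlobVolumeSpec(seed=0))
    test_v, test_c = ic.gen_blob_volume(ic.BlobVolumeSpec(seed=1))
    return train_v, train_c, test_v, test_c


@pytest.fixture(scope="session")
def counting_model(blob_pair):
    """A patch classifier trained on labelled ROIs of the training volume."""
    from imagechain.chains import _extract_all
    from imagechain.synth import sample_background_points
    from imagechain.volume import extract_patch, patch_as_volume

    train_v, train_c, _, _ = blob_pair
    geom = ic.PatchGeometry(3, 3, 2)
    rng = np.random.default_rng(7)
    pos = list(train_c)
    while len(pos) < 50:  # jittered copies of true centres
        c = train_c[rng.integers(len(train_c))]
        pos.append(ic.Coordinate(c.x + int(rng.integers(-1, 2)),
                                 c.y + int(rng.integers(-1, 2)),
                                 c.z + int(rng.integers(-1, 2))))
    neg = sample_background_points(train_v, train_c, n=50,
                                   min_distance=8.0, seed=100)
    extractors = [ic.make_extractor("aniso-wavelet-3d"),
                  ic.make_extractor("hu3d")]
    rows, labels, tags = [], [], None
    for coord, label in [(p, "pos") for p in pos] + \
                        [(n, "neg") for n in neg]:
        patch = patch_as_volume(extract_patch(train_v, coord, geom))
        vec, tags = _extract_all(extractors, patch, "fixture")
        rows.append(vec)
        labels.append(label)
    matrix = ic.FeatureMatrix(np.vstack(rows), tags, labels=labels)
    chain = ic.AlgorithmChain(
        "aniso+svm", extractors,
        classifier=ic.ClassifierSpec(kind="svm-linear", C=1.0))
    classifier = ic.fit_classifier(chain.classifier, matrix)
    model = ic.TrainedModel(
        chain=chain, classifier=classifier,
        selected_columns=list(range(matrix.n_features)),
        column_names=list(matrix.columns), classes=classifier.classes,
        geometry=geom)
    return model


@pytest.fixture(scope="session")
def roi_matrix(blob_pair):
    """Labelled ROI feature matrix of the training volume (pos/neg)."""
    from imagechain.chains import _extract_all
    from imagechain.synth import sample_background_points
    from imagechain.volume import extract_patch, patch_as_volume

    train_v, train_c, _, _ = blob_pair
    geom = ic.PatchGeometry(3, 3, 2)
    neg = sample_background_points(train_v, train_c, n=20,
                                   min_distance=8.0, seed=3)
    extractors = [ic.make_extractor("aniso-wavelet-3d")]
    rows, labels, tags = [], [], None
    for coord, label in [(c, "pos") for c in train_c] + \
                        [(n, "neg") for n in neg]:
        patch = patch_as_volume(extract_patch(train_v, coord, geom))
        vec, tags = _extract_all(extractors, patch, "fixture")
        rows.append(vec)
        labels.append(label)
    return ic.FeatureMatrix(np.vstack(rows), tags, labels=labels)
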