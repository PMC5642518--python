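import numpy as np
import pytest

import canes


@pytest.fixture(scope="session")
def cldn_ds():
    """Gastric-like toy dataset with a planted three-claudin panel."""
    return canes.preset_cldn_toy(seed=17)


@pytest.fixture(scope="session")
def svm_only():
    return canes.default_classifiers(seed=1, names=("svm",))


@pytest.fixture(scope="session")
def cart_only():
    return canes.default_classifiers(seed=1, names=("cart",))


@pytest.fixture
def tiny_files(tmp_path):
    """3-probe x 4-sample TSV matrix + labels + annotation on disk."""
    matrix = tmp_path / "m.tsv"
    matrix.write_text(
        "probe_id\ts1\ts2\ts3\ts4\n"
        "p1\t1.0\tNA\t3.0\t4.0\n"
        "p2\t2.0\t2.5\t2.0\t2.2\n"
        "p3\t5.0\t5.1\t4.9\t5.2\n"
    )
    labels = tmp_path / "l.tsv"
    labels.write_text("s1\tcancer\ns2\tcancer\ns3\tnormal\ns4\tnormal\n")
    annotation = tmp_path / "a.tsv"
    annotation.write_text("p1\tCLDN1\np2\tCLDN1\np3\tKRT8\n")
    return matrix, labels, annotation


def random_confusion(rng):
    tp, tn, fp, fn = (int(v) for v in rng.integers(0, 60, size=4))
    return canes.ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def auc_concordance_oracle(scores, labels):
    """Brute-force pairwise concordance probability with half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = conc = 0.0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                conc += 1
            elif a == b:
                conc += 0.5
    return conc / total
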