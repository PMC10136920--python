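import numpy as np
import pytest

import apneaflow as af

CORPUS_SEED = 7


def match_peaks(detected: np.ndarray, truth: np.ndarray, tol_samples: int):
    """Greedy one-to-one matching of detected to true peaks.

    Returns (tp, fp, fn).
    """
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    used = set()
    tp = 0
    for p in truth:
        if detected.size == 0:
            break
        d = np.abs(detected - p)
        order = np.argsort(d)
        for k in order:
            if d[k] > tol_samples:
                break
            if k not in used:
                used.add(int(k))
                tp += 1
                break
    return tp, detected.size - tp, truth.size - tp


@pytest.fixture(scope="session")
def trained_corpus():
    """Window classifier trained on the shipped synthetic corpus, plus
    the raw feature matrix it was built from."""
    corpus = af.make_training_corpus(seed=CORPUS_SEED, n_records=16,
                                     minutes_per_record=6)
    model, metrics, (raw, labels, columns) = af.train_from_corpus(
        corpus, seed=CORPUS_SEED)
    return {"model": model, "metrics": metrics, "raw": raw,
            "labels": labels, "columns": columns}
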