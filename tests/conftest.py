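import numpy as np
import pytest

from sparecg import synthetic_ecg as se


@pytest.fixture(scope="session")
def clean_ecg():
    """Noise-free, perfectly periodic synthetic ECG (1 s beats, 10 s)."""
    params = se.SyntheticECGParams(mean_rr=1.0, rr_sd=0.0, noise_sd=0.0,
                                   baseline_amp=0.0, seed=0)
    return se.generate_ecg(params, record_id="clean", patient_id="p_clean")


@pytest.fixture(scope="session")
def realistic_ecg():
    """Synthetic ECG with RR variability, baseline wander and noise."""
    params = se.SyntheticECGParams(seed=7)
    return se.generate_ecg(params, record_id="real", patient_id="p_real")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def toy_feature_table(n_per_class=5, n_features=4, separation=0.0, seed=0,
                      records_per_patient=1):
    """Two-class Gaussian feature table with a planted separating direction."""
    from sparecg.ml_harness import FeatureTable

    rng = np.random.default_rng(seed)
    rows, ids, pids, labels = [], [], [], []
    for cls, label in ((0, "case"), (1, "control")):
        for i in range(n_per_class):
            pid = f"{label}_p{i}"
            centre = separation if label == "case" else 0.0
            for r in range(records_per_patient):
                rows.append(rng.normal(centre, 1.0, n_features))
                ids.append(f"{pid}_r{r}")
                pids.append(pid)
                labels.append(label)
    return FeatureTable(record_ids=ids, patient_ids=pids, labels=labels,
                        X=np.vstack(rows),
                        feature_names=[f"f{j}" for j in range(n_features)])
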