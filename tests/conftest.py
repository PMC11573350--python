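import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def pte_bruteforce(phi_x, phi_y, tau, n_bins):
    """Independent triple-loop plug-in conditional MI over histogram cells.

    Deliberately naive: per-sample bin lookup by linear scan and an explicit
    triple loop over (future, present, driver) cells.
    """
    edges = [-np.pi + 2 * np.pi * b / n_bins for b in range(n_bins + 1)]

    def binof(v):
        for b in range(n_bins):
            if edges[b] <= v < edges[b + 1]:
                return b
        return n_bins - 1

    m = len(phi_x)
    counts = np.zeros((n_bins, n_bins, n_bins))
    for t in range(m - tau):
        counts[binof(phi_y[t + tau]), binof(phi_y[t]), binof(phi_x[t])] += 1
    total = counts.sum()
    out = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            for k in range(n_bins):
                c = counts[i, j, k]
                if c == 0:
                    continue
                p_ijk = c / total
                p_jk = counts[:, j, k].sum() / total
                p_ij = counts[i, j, :].sum() / total
                p_j = counts[:, j, :].sum() / total
                out += p_ijk * np.log(p_ijk * p_j / (p_jk * p_ij))
    return out


@pytest.fixture(scope="session")
def hub_session():
    """One preprocessed synthetic session with a known AI-driven hub."""
    import warnings

    from ieegflow import pipeline, synth

    cfg = pipeline.ai_hub_config(seed=42, strength=0.8, lag=25)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.preprocess_session(synth.make_session(cfg))


def mixed_table(rng, d=0.0, n_subjects=10, n_pairs=10, sd_subject=0.5, sd_resid=1.0):
    """Observation table drawn from the mixed model's own assumptions."""
    n = n_subjects * n_pairs * 2
    subj = np.repeat([f"S{s:02d}" for s in range(n_subjects)], n_pairs * 2)
    b = np.repeat(rng.normal(0, sd_subject, n_subjects), n_pairs * 2)
    cond = np.tile(["fwd", "rev"], n_subjects * n_pairs)
    shift = np.where(cond == "fwd", d / 2, -d / 2)
    return pd.DataFrame(
        {"value": b + shift + rng.normal(0, sd_resid, n), "condition": cond, "subject": subj}
    )
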