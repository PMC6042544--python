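"""Shared fixtures: small simulated datasets and fast fit configurations."""

import numpy as np
import pytest

import lctmflow as lf


@pytest.fixture(scope="session")
def fast_fit() -> lf.FitConfig:
    return lf.FitConfig(n_starts=2, seed=7, max_iter=300)


@pytest.fixture(scope="session")
def two_class_F():
    """Well-separated 2-class model-F simulation (N=400) and its fit."""
    cfg = lf.two_class_config(n_subjects=400, structure_code="F", seed=11)
    sim = lf.simulate(cfg)
    model = lf.fit(sim.dataset, cfg.structure, lf.FitConfig(n_starts=2, seed=5))
    return cfg, sim, model


@pytest.fixture(scope="session")
def three_class_sim():
    from lctmflow.synthetic import three_class_config
    cfg = three_class_config(n_subjects=500, seed=23)
    return cfg, lf.simulate(cfg)


def make_fitted(structure_code="A", n_classes=2, fixed_degree=0, beta=None,
                pi=None, sigma2=(1.0,), posterior=None, n_subjects=None,
                loglik=-100.0, B=None, omega=None, B_by_class=None,
                time_transform=None, converged=True) -> lf.FittedModel:
    """Hand-built FittedModel for diagnostics tests that need no EM fit."""
    tt = time_transform or lf.TimeTransform.identity()
    structure = lf.ModelStructure(structure_code=structure_code, n_classes=n_classes,
                                  fixed_degree=fixed_degree, time_transform=tt)
    K = n_classes
    if beta is None:
        beta = np.zeros((K, fixed_degree + 1))
    if pi is None:
        pi = np.full(K, 1.0 / K)
    if posterior is None:
        N = n_subjects or 4
        posterior = np.tile(np.asarray(pi, dtype=float), (N, 1))
    posterior = np.asarray(posterior, dtype=float)
    N = posterior.shape[0]
    return lf.FittedModel(
        structure=structure, beta=np.asarray(beta, dtype=float),
        pi=np.asarray(pi, dtype=float),
        B=None if B is None else np.asarray(B, dtype=float),
        omega=None if omega is None else np.asarray(omega, dtype=float),
        B_by_class=None if B_by_class is None else np.asarray(B_by_class, dtype=float),
        sigma2=np.asarray(sigma2, dtype=float), loglik=loglik, n_subjects=N,
        n_params=lf.count_parameters(structure), posterior=posterior,
        assignment=np.argmax(posterior, axis=1),
        subject_ids=np.arange(1, N + 1).astype(object),
        converged=converged, n_iter=1, n_starts_used=1, seed=0)
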