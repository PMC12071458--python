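"""Latent construction, controlled generation, and property grids."""

import numpy as np
import pytest

from icvae.generator import (
    GenerationRequest,
    apply_error_bound,
    generate,
    grid_steps,
    make_latent,
    property_sweep,
)
from icvae.properties import fit_spec, scale


@pytest.fixture()
def hba_spec():
    return [fit_spec("HBA", 0, 10)]


def test_make_latent_noise_zero_exact(hba_spec):
    req = GenerationRequest(targets={"HBA": 5}, n=4, noise_scale=0.0, seed=1)
    z, C = make_latent(req, hba_spec, K=8, rng=np.random.default_rng(1))
    assert np.all(z[:, 0] == 250.0)  # 50 * 5
    assert np.all(C[:, 0] == 250.0)


def test_make_latent_vmin_maps_to_zero(hba_spec):
    req = GenerationRequest(targets={"HBA": 0}, n=2, noise_scale=0.0, seed=1)
    z, _ = make_latent(req, hba_spec, K=8, rng=np.random.default_rng(1))
    assert np.all(z[:, 0] == 0.0)


def test_make_latent_seeded_determinism(hba_spec):
    req = GenerationRequest(targets={"HBA": 3}, n=5, seed=9)
    z1, _ = make_latent(req, hba_spec, K=8, rng=np.random.default_rng(9))
    z2, _ = make_latent(req, hba_spec, K=8, rng=np.random.default_rng(9))
    assert np.array_equal(z1, z2)


def test_make_latent_unknown_property(hba_spec):
    req = GenerationRequest(targets={"QED": 0.5}, n=1)
    with pytest.raises(KeyError, match="QED"):
        make_latent(req, hba_spec, K=8, rng=np.random.default_rng(0))


def test_request_validation():
    with pytest.raises(ValueError):
        GenerationRequest(targets={"HBA": 1}, n=0)
    with pytest.raises(ValueError):
        GenerationRequest(targets={"HBA": 1}, noise_scale=-1)


@pytest.mark.parametrize(
    "start, stop, step, count",
    [
        (210, 490, 20, 15),   # MW
        (0.2, 5.8, 0.4, 15),  # logP
        (0.05, 0.61, 0.04, 15),  # QED
        (1.2, 6.8, 0.4, 15),  # SAS
        (18, 74, 4, 15),      # TPSA
        (0, 10, 1, 11),       # HBA
        (0, 5, 1, 6),         # HBD
        (170, 350, 10, 19),   # MW arm of the paired grid
    ],
)
def test_grid_step_counts(start, stop, step, count):
    g = grid_steps(start, stop, step)
    assert len(g) == count
    assert g[0] == pytest.approx(start)
    assert g[-1] == pytest.approx(stop)


def test_grid_rejects_bad_step():
    with pytest.raises(ValueError):
        grid_steps(0, 10, -1)


def test_generate_greedy_is_deterministic(trained_toy):
    model, vocab, specs = trained_toy.model, trained_toy.vocab, trained_toy.specs
    req = GenerationRequest(targets={"HBA": 2}, n=10, seed=5)
    a = generate(model, vocab, specs, req)
    b = generate(model, vocab, specs, req)
    assert a.smiles.tolist() == b.smiles.tolist()
    assert len(a) == 10
    assert a.achieved_HBA[~a.valid].isna().all()


def test_generate_rejects_unconditioned_property(trained_toy):
    req = GenerationRequest(targets={"QED": 0.5}, n=1)
    with pytest.raises(KeyError):
        generate(trained_toy.model, trained_toy.vocab, trained_toy.specs, req)


def test_sweep_row_count_and_columns(trained_toy):
    model, vocab, specs = trained_toy.model, trained_toy.vocab, trained_toy.specs
    spec = specs[0]
    table = property_sweep(
        model, vocab, specs, {"HBA": (1, 5, 1)}, n_per_step=3, seed=0
    )
    assert len(table) == 5 * 3
    assert {"step", "smiles", "valid", "target_HBA", "achieved_HBA",
            "abs_error_HBA"} <= set(table.columns)
    assert sorted(table.target_HBA.unique()) == [1, 2, 3, 4, 5]


def test_paired_two_property_sweep_resamples_to_longest(trained_toy, monkeypatch):
    """MW 170-350/10 with TPSA 10-90/10 -> 19 paired steps."""
    from icvae import generator as gen_mod

    calls = []

    def fake_generate(model, vocab, specs, request):
        calls.append(dict(request.targets))
        import pandas as pd
        return pd.DataFrame(
            {"smiles": ["C"] * request.n, "valid": [True] * request.n,
             "achieved_MW": [0.0] * request.n, "achieved_TPSA": [0.0] * request.n}
        )

    monkeypatch.setattr(gen_mod, "generate", fake_generate)
    specs = [fit_spec("MW", 0, 500), fit_spec("TPSA", 0, 200)]
    table = gen_mod.property_sweep(
        trained_toy.model, trained_toy.vocab, specs,
        {"MW": (170, 350, 10), "TPSA": (10, 90, 10)}, n_per_step=2, seed=0,
    )
    assert len(calls) == 19
    mws = [c["MW"] for c in calls]
    tpsas = [c["TPSA"] for c in calls]
    assert mws == pytest.approx(list(np.arange(170, 351, 10)))
    assert tpsas == pytest.approx(list(np.linspace(10, 90, 19)))
    assert len(table) == 19 * 2


def test_empty_grid_rejected(trained_toy):
    with pytest.raises(ValueError):
        property_sweep(trained_toy.model, trained_toy.vocab, trained_toy.specs, {})


def test_apply_error_bound_filters(trained_toy):
    table = property_sweep(
        trained_toy.model, trained_toy.vocab, trained_toy.specs,
        {"HBA": (1, 3, 1)}, n_per_step=5, seed=3,
        noise_scale=0.5,
    )
    kept = apply_error_bound(table, {"HBA": 1.0})
    assert kept.valid.all()
    assert (kept.abs_error_HBA <= 1.0).all()
    assert len(kept) <= len(table)
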