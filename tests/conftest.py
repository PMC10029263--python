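import warnings

import pytest

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*feature names.*")

from mutarules import chem_io, mmpa_engine
from mutarules import applicability_domain as ad
from mutarules import mutagenicity_model as mm
from mutarules import rule_application, rule_evaluation
from mutarules.synthetic_fixtures import FixtureSpec, generate

# Seeds fixed once for the whole suite; study conditions for the end-to-end
# checks are the generator defaults (n=400, noise 0.05).
FIXTURE_SEED = 11
MODEL_SEED = 23


@pytest.fixture(scope="session")
def fixture_small():
    """120-molecule synthetic set for unit-scale chemistry tests."""
    return generate(FixtureSpec(n_molecules=120, seed=7))


@pytest.fixture(scope="session")
def fixture_default():
    """Default-condition synthetic set: n=400, 5% label noise."""
    return generate(FixtureSpec(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def determinism_runs(tmp_path_factory):
    """The same pipeline config executed twice into separate directories."""
    from mutarules.workflow_cli import RunConfig, run_pipeline

    outs = []
    for tag in ("a", "b"):
        cfg = RunConfig(
            out_dir=str(tmp_path_factory.mktemp(f"run_{tag}") / "run"),
            seed=5,
            fixture_n=150,
            folds=3,
            radii=[0, 1],
            min_coverage=0.5,
            min_usage=3,
        )
        outs.append(run_pipeline(cfg))
    return outs


@pytest.fixture(scope="session")
def trained_pipeline(fixture_default):
    """Full pipeline run at default conditions, shared across tests.

    Derives rules from the whole curated set, trains the five-member
    consensus stack on the train split, fits the applicability domain
    against the test split, and scores all radius-0 products.
    """
    dataset, manifest = fixture_default
    train, test = chem_io.split(dataset, 0.1, seed=MODEL_SEED)

    frags = mmpa_engine.fragment_dataset(dataset)
    pairs = mmpa_engine.index_pairs(frags)
    rules = mmpa_engine.derive_rules(pairs, dataset.labels)

    specs = mm.default_specs()
    for spec in specs:
        mm.train_base(train, spec, folds=5, seed=MODEL_SEED)
    model = mm.stack_consensus(train, specs, folds=5, seed=MODEL_SEED)

    train_fps, _ = mm.dataset_arrays(train, "ecfp")
    test_fps, _ = mm.dataset_arrays(test, "ecfp")
    params, ad_info = ad.grid_search_ad(
        model, train_fps, test, test_fps,
        k_grid=[1, 3, 5], z_grid=[0.5, 1.0, 2.0], min_coverage=0.75,
    )

    generated, tally = rule_application.generate_candidates(
        dataset.positives(), rules, 0, model, params, train_fps
    )
    evaluations = rule_evaluation.score_rules(generated)
    return {
        "dataset": dataset,
        "manifest": manifest,
        "train": train,
        "test": test,
        "rules": rules,
        "specs": specs,
        "model": model,
        "params": params,
        "ad_info": ad_info,
        "train_fps": train_fps,
        "test_fps": test_fps,
        "generated": generated,
        "tally": tally,
        "evaluations": evaluations,
    }
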