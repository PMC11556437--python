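import numpy as np
import pytest

from radiolysis_irt import RunConfig, SpurModel, build_chemical_table


@pytest.fixture(scope="session")
def table_25_7():
    return build_chemical_table(25.0, 7.0)


@pytest.fixture(scope="session")
def spur_model():
    return SpurModel.default()


@pytest.fixture()
def small_config():
    return RunConfig(n_runs=2, n_histories_per_run=100, rng_seed=11)


@pytest.fixture(scope="session")
def zero_rate_overrides(tmp_path_factory):
    """Override file setting every default rate constant to zero."""
    from radiolysis_irt.parameters import load_reactions

    lines = [
        "id,reactants,products,type_tag,kinetics_class,background,k_form,k25,k_p1"
    ]
    for rxn in load_reactions():
        lines.append(
            ",".join(
                [
                    rxn.id,
                    "|".join(rxn.reactants),
                    "|".join(rxn.products),
                    str(rxn.type_tag),
                    rxn.kinetics_class,
                    rxn.background or "",
                    "none",
                    "0.0",
                    "0.0",
                ]
            )
        )
    path = tmp_path_factory.mktemp("overrides") / "all_zero.csv"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
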