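import pytest

import reprometh as rm


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 2000 probes, groups 3/5/9/6, seed 1."""
    config = rm.SimulationConfig()
    matrix, sheet, annotation, truth = rm.generate_dataset(config)
    return config, matrix, sheet, annotation, truth


@pytest.fixture(scope="session")
def default_analysis(default_dataset):
    """Both differential analyses plus classifications on the default study."""
    _, matrix, sheet, annotation, truth = default_dataset
    diff_shared = rm.call_differential(
        matrix, sheet, (rm.Group.Y_IPSC, rm.Group.T_IPSC), rm.Group.ESC
    )
    diff_factor = rm.call_differential(matrix, sheet, rm.Group.Y_IPSC, rm.Group.T_IPSC)
    shared = rm.shared_aberrations(matrix, sheet, diff_shared)
    factor = rm.factor_specific_aberrations(matrix, sheet, diff_factor)
    return {
        "diff_shared": diff_shared,
        "diff_factor": diff_factor,
        "shared": shared,
        "factor": factor,
    }
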