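import numpy as np
import pytest

from dcekit import PipelineConfig, analyze_patient, default_phantom_spec, generate_phantom

N_NOISY_REPLICATES = 200
NOISE_SD = 5.0  # 5% of the 100-unit baseline intensity


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = default_phantom_spec()
    series, mask, gt = generate_phantom(spec)
    return spec, series, mask, gt


@pytest.fixture(scope="session")
def phantom_result(noiseless_phantom):
    _, series, mask, gt = noiseless_phantom
    return analyze_patient(series, mask, PipelineConfig()), gt


@pytest.fixture(scope="session")
def noisy_slope_errors():
    """Relative slope-recovery errors over noisy phantom replicates.

    Regenerates the default phantom with 5%-of-baseline Gaussian noise and
    a fresh seed per replicate, runs the full chain, and records the
    relative error of every recovered nonzero slope against ground truth.
    """
    config = PipelineConfig()
    errors = {"TSL_in": [], "TSL_out": [], "NAT_in": []}
    for i in range(N_NOISY_REPLICATES):
        spec = default_phantom_spec(noise_sd=NOISE_SD, seed=10_000 + i)
        series, mask, gt = generate_phantom(spec)
        result = analyze_patient(series, mask, config)
        feats = result["features"]
        errors["TSL_in"].append(
            abs(feats["TSL"].wash_in_slope - gt["TSL"].wash_in_slope)
            / gt["TSL"].wash_in_slope
        )
        errors["TSL_out"].append(
            abs(feats["TSL"].wash_out_slope - gt["TSL"].wash_out_slope)
            / abs(gt["TSL"].wash_out_slope)
        )
        errors["NAT_in"].append(
            abs(feats["NAT"].wash_in_slope - gt["NAT"].wash_in_slope)
            / gt["NAT"].wash_in_slope
        )
    return {k: np.asarray(v) for k, v in errors.items()}
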