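import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# Printed validation-table cells of the published assay, used as worked
# examples: (mean found ng/mL, nominal ng/mL, reported accuracy %).
TABLE2_ACCURACY_CELLS = [
    # metformin intra-day / inter-day
    (47.24, 50, 94.48),
    (152.17, 150, 101.45),
    (943.81, 1000, 94.38),
    (3667.95, 4000, 91.70),
    (48.55, 50, 97.10),
    (161.15, 150, 107.43),
    (935.77, 1000, 93.58),
    (3734.26, 4000, 93.36),
    # canagliflozin intra-day / inter-day
    (11.31, 10, 113.10),
    (32.73, 30, 109.10),
    (181.30, 200, 90.65),
    (768.06, 800, 96.01),
    (11.12, 10, 111.20),
    (29.95, 30, 99.83),
    (176.28, 200, 88.14),
    (738.32, 800, 92.29),
]

TABLE4_ACCURACY_CELLS = [
    # short term (CFZ LQC/HQC, MET LQC/HQC)
    (26.30, 30, 87.67),
    (704.72, 800, 88.09),
    (132.38, 150, 88.25),
    (3565.06, 4000, 89.13),
    # freeze-thaw
    (28.61, 30, 95.37),
    (713.42, 800, 89.18),
    (141.10, 150, 94.07),
    (3552.69, 4000, 88.82),
    # dry extract
    (28.54, 30, 95.13),
    (696.46, 800, 87.06),
    (139.01, 150, 92.67),
    (3699.81, 4000, 92.50),
    # processed sample
    (28.12, 30, 93.73),
    (698.63, 800, 87.33),
    (134.03, 150, 89.35),
    (3836.46, 4000, 95.91),
    # long term
    (29.77, 30, 99.23),
    (687.82, 800, 85.98),
    (130.4, 150, 86.93),
    (3619.81, 4000, 90.50),
]

# Per-level extraction recoveries (%) and their reported across-level means.
RECOVERY_MET = ([98.55, 97.69, 98.40], 98.21)
RECOVERY_CFZ = ([90.12, 94.04, 98.79], 94.32)

# Published calibration lines: response ratio = slope * ng/mL + intercept.
MET_LINE = (0.0016, -0.0088)
CFZ_LINE = (0.0056, -0.0036)
MET_LEVELS = [50, 100, 250, 500, 1000, 2000, 4000, 5000]
CFZ_LEVELS = [10, 20, 50, 100, 200, 400, 800, 1000]


@pytest.fixture
def gaussian_chrom():
    """Factory for a single-transition Gaussian chromatogram."""
    from plasmaquant.chromatography import MRMTransition
    from plasmaquant.simulate import simulate_chromatogram

    def make(amplitude=1000.0, rt=0.9, sigma=0.05, noise_sd=0.0, baseline=0.0,
             seed=0, analyte="X"):
        tr = MRMTransition(analyte, 200.0, 100.0, rt)
        return simulate_chromatogram(
            [tr],
            {analyte: amplitude},
            noise_sd=noise_sd,
            seed=seed,
            response_factor=1.0,
            peak_sigma_min=sigma,
            baseline=baseline,
        )[0]

    return make


@pytest.fixture
def met_standards():
    """Noise-free calibration standards on the metformin response line."""
    from plasmaquant.calibration import CalibrationStandard

    slope, intercept = MET_LINE
    return [
        CalibrationStandard(nominal=x, response_ratio=slope * x + intercept)
        for x in MET_LEVELS
    ]
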