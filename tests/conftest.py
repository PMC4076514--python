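import pytest
from hypothesis import HealthCheck, settings

import quadfluor as qf
from quadfluor.synth import RenderParams

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_profiles():
    """A reduced four-subject cohort: 2 runs x 50 cells on 512x512 fields."""
    return tuple(
        qf.PatientProfile(
            p.group_label,
            ci_porin_mult=p.ci_porin_mult,
            civ_porin_mult=p.civ_porin_mult,
            porin_factor=p.porin_factor,
            frac_ci_deficient=p.frac_ci_deficient,
            frac_civ_deficient=p.frac_civ_deficient,
            cells_per_section=50,
            runs=2,
        )
        for p in qf.make_default_profiles()
    )


SMALL_RENDER = RenderParams(image_shape=(512, 512), speckle_count=10)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small simulated cohort on disk (4 subjects x 2 runs x 1 section)."""
    root = tmp_path_factory.mktemp("cohort")
    qf.simulate_cohort(small_profiles(), seed=11, output_dir=root, render_params=SMALL_RENDER)
    return root


@pytest.fixture(scope="session")
def small_results(small_dataset):
    """Full analysis of the small cohort."""
    return qf.analyze_cohort(small_dataset)
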