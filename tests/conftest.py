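import pytest

from imprintscan import (
    AmpliconDef,
    AmpliconKind,
    Parent,
    PanelConfig,
    Role,
    SampleSpec,
    build_baseline,
    default_panel,
    simulate_sample_pair,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def mini_panel():
    """One DMR plus two references, hand-computable relative areas."""
    return PanelConfig(
        name="mini",
        version="1",
        amplicons=(
            AmpliconDef(name="dmr", locus="DMR1", expected_size=100,
                        size_tolerance=2, kind=AmpliconKind.DMR,
                        chrom_band="11p15",
                        methylated_parent=Parent.MATERNAL),
            AmpliconDef(name="ref1", locus="R1", expected_size=150,
                        size_tolerance=2, kind=AmpliconKind.REFERENCE),
            AmpliconDef(name="ref2", locus="R2", expected_size=200,
                        size_tolerance=2, kind=AmpliconKind.REFERENCE),
        ),
    )


@pytest.fixture(scope="session")
def noise_free_controls(panel):
    specs = [SampleSpec(sample_id=f"control_{i}", role=Role.CONTROL)
             for i in range(1, 6)]
    return [simulate_sample_pair(s, panel)[0] for s in specs]


@pytest.fixture(scope="session")
def noise_free_baseline(panel, noise_free_controls):
    return build_baseline(noise_free_controls, panel)
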