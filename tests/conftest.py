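import pytest

import pahrisk as pr


@pytest.fixture(scope="session")
def survey():
    """The bundled 7-herb x 16-PAH survey table."""
    return pr.load_chm_survey()


@pytest.fixture()
def point_factors():
    """Unit factors chosen so the deterministic ILCR equals the TEQ."""
    return pr.ExposureFactors(
        group="unit",
        dr=pr.DistributionSpec.point(1.0),
        csf=pr.DistributionSpec.point(1.0),
        ef=pr.DistributionSpec.point(365.0),
        ed=pr.DistributionSpec.point(1.0),
        bw=pr.DistributionSpec.point(1.0),
        at=pr.DistributionSpec.point(365.0),
    )


def make_factors(**overrides):
    """Point exposure factors with selective overrides (values or specs)."""
    group = overrides.pop("group", "adult")
    defaults = dict(dr=5.0, csf=7.3, ef=365.0, ed=30.0, bw=60.0, at=25550.0)
    specs = {}
    for key, value in {**defaults, **overrides}.items():
        if isinstance(value, pr.DistributionSpec):
            specs[key] = value
        else:
            specs[key] = pr.DistributionSpec.point(float(value))
    return pr.ExposureFactors(group=group, **specs)
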