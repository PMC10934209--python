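"""Packaged datasets."""

from __future__ import annotations

from importlib import resources

from .table import ConcentrationTable, read_concentration_table


def survey_path() -> str:
    """Filesystem path of the bundled herbal-medicine PAH survey CSV."""
    return str(resources.files("pahrisk.data") / "chm_survey.csv")


def load_chm_survey() -> ConcentrationTable:
    """The bundled survey: 7 herbal medicines x 16 EPA PAHs, mean
    concentrations in µg/kg with per-cell RSDs and "nd" non-detects."""
    return read_concentration_table(survey_path())


def exposure_template_path() -> str:
    """Filesystem path of the exposure-factor configuration template."""
    return str(resources.files("pahrisk.data") / "exposure_template.yaml")
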