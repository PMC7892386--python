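"""Shared fixtures: published example rows and small synthetic inputs.

``PUBLISHED_ROWS`` transcribes the worked examples of gene modulations with
discrepant and with convergent evidence (the EZH2/MINK1/TTR/CD9/TLR4/RHEB
discrepancy examples and the SIRT1/FYN/TNFRSF11B/ADAMTS5 multi-evidence
examples).  Each tuple is (gene, pmid, intervention, activity_change,
approach, model, observed_effect, printed_inferred_effect, species).

The three TTR rows carry printed inferred values that contradict the
inference rule every other row follows (the block appears transposed in
print), so ``anomalous=True`` marks them for exclusion from inferred-label
assertions; they still participate in consensus-level checks.
"""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from oatargets.curation import Observation, read_observations

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

# gene, pmid, intervention, activity, approach, model, observed, inferred, anomalous
PUBLISHED_ROWS = [
    # --- discrepancy examples ---
    ("EZH2", "30327434", "Knockout", "removal", "genetic", "spontaneous", "no_effect", "no_effect", False),
    ("EZH2", "31910305", "Knockout", "removal", "genetic", "surgical - MM", "detrimental", "protective", False),
    ("EZH2", "27539752", "EPZ005687", "inhibition", "exogenous", "surgical - ACLT", "protective", "detrimental", False),
    ("MINK1", "31647983", "Knockout", "removal", "genetic", "spontaneous", "protective", "detrimental", False),
    ("MINK1", "31647983", "Knockout", "removal", "genetic", "surgical - DMM", "detrimental", "protective", False),
    ("TTR", "28941045", "Knockout", "removal", "genetic", "surgical - DMM", "detrimental", "detrimental", True),
    ("TTR", "28941045", "Knockout", "removal", "genetic", "spontaneous", "detrimental", "detrimental", True),
    ("TTR", "28941045", "Overexpression", "overexpression", "genetic", "surgical - DMM", "detrimental", "protective", True),
    ("CD9", "27784871", "Knockout", "removal", "genetic", "surgical - MML+MCL", "no_effect", "no_effect", False),
    ("CD9", "27784871", "Knockout", "removal", "genetic", "spontaneous", "protective", "detrimental", False),
    ("TLR4", "31044181", "Knockout", "removal", "genetic", "high_fat_diet", "protective", "detrimental", False),
    ("TLR4", "26245312", "Knockout", "removal", "genetic", "surgical - DMM", "no_effect", "no_effect", False),
    ("TLR4", "24703622", "Knockout", "removal", "genetic", "surgical - DMM+MM", "no_effect", "no_effect", False),
    ("RHEB", "29991473", "Knockout", "removal", "genetic", "chemical - collagenase", "protective", "detrimental", False),
    ("RHEB", "31229684", "Overexpression", "overexpression", "genetic", "surgical - DMM", "protective", "protective", False),
    # --- convergent genetic + exogenous evidence examples ---
    ("SIRT1", "23723318", "Knockout", "removal", "genetic", "surgical - DMM+MM", "detrimental", "protective", False),
    ("SIRT1", "32665267", "Knockout", "removal", "genetic", "surgical - DMM", "detrimental", "protective", False),
    ("SIRT1", "32499111", "Knockout", "removal", "genetic", "surgical - DMM", "detrimental", "protective", False),
    ("SIRT1", "32499111", "Knockout", "removal", "genetic", "spontaneous", "detrimental", "protective", False),
    ("SIRT1", "23723318", "Knockout", "removal", "genetic", "spontaneous", "detrimental", "protective", False),
    ("SIRT1", "23587642", "Knockout", "removal", "genetic", "spontaneous", "detrimental", "protective", False),
    ("SIRT1", "23124828", "Mutation", "inhibition", "genetic", "spontaneous", "detrimental", "protective", False),
    ("SIRT1", "22258484", "Haploinsufficiency", "deficiency", "genetic", "spontaneous", "detrimental", "protective", False),
    ("SIRT1", "29922443", "SRT1720", "activation", "exogenous", "surgical - DMM", "protective", "protective", False),
    ("SIRT1", "31989845", "SRT2104", "activation", "exogenous", "surgical - DMM", "protective", "protective", False),
    ("FYN", "29555825", "Knockout", "removal", "genetic", "spontaneous", "protective", "detrimental", False),
    ("FYN", "29555825", "Knockout", "removal", "genetic", "surgical - DMM", "protective", "detrimental", False),
    ("FYN", "31534047", "Knockout", "removal", "genetic", "surgical - DMM", "protective", "detrimental", False),
    ("FYN", "29555825", "PP1", "inhibition", "exogenous", "surgical - DMM", "protective", "detrimental", False),
    ("FYN", "29555825", "AZD0530", "inhibition", "exogenous", "surgical - DMM", "protective", "detrimental", False),
    ("TNFRSF11B", "30623241", "Knockout", "removal", "genetic", "surgical - TMJ", "detrimental", "protective", False),
    ("TNFRSF11B", "27541035", "Knockout", "removal", "genetic", "spontaneous", "detrimental", "protective", False),
    ("TNFRSF11B", "26018435", "Knockout", "removal", "genetic", "spontaneous", "detrimental", "protective", False),
    ("TNFRSF11B", "17907189", "Haploinsufficiency", "deficiency", "genetic", "spontaneous", "detrimental", "protective", False),
    ("TNFRSF11B", "17907189", "Haploinsufficiency", "deficiency", "genetic", "surgical - DMM", "detrimental", "protective", False),
    ("TNFRSF11B", "17907189", "Protein", "increase", "exogenous", "surgical - DMM", "protective", "protective", False),
    ("TNFRSF11B", "18668550", "Protein", "increase", "exogenous", "surgical - DMM+MM", "protective", "protective", False),
    ("TNFRSF11B", "23723320", "Protein", "increase", "exogenous", "chemical - MIA", "protective", "protective", False),
    ("ADAMTS5", "21337391", "Knockout", "removal", "genetic", "surgical - DMM", "protective", "detrimental", False),
    ("ADAMTS5", "21337391", "Knockout", "removal", "genetic", "mechanical - treadmill", "protective", "detrimental", False),
    ("ADAMTS5", "19010693", "Knockout", "removal", "genetic", "surgical - DMM", "protective", "detrimental", False),
    ("ADAMTS5", "17968948", "Knockout", "removal", "genetic", "surgical - DMM", "protective", "detrimental", False),
    ("ADAMTS5", "15800624", "Knockout", "removal", "genetic", "surgical - DMM", "protective", "detrimental", False),
    ("ADAMTS5", "23954517", "Antibody", "inhibition", "exogenous", "genetic_susceptibility - STR/ort", "protective", "detrimental", False),
    ("ADAMTS5", "26410555", "Antibody", "inhibition", "exogenous", "surgical - DMM", "protective", "detrimental", False),
    ("ADAMTS5", "28120109", "siRNA", "knockdown", "exogenous", "surgical - DMM", "protective", "detrimental", False),
]

def published_frame() -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": gene,
                "pmid": pmid,
                "intervention": intervention,
                "activity_change": activity,
                "approach": approach,
                "model": model,
                "observed_effect": observed,
                "specificity": "Global",
                "species": "Mouse",
            }
            for (gene, pmid, intervention, activity, approach, model, observed,
                 _inferred, _anom) in PUBLISHED_ROWS
        ]
    )


@pytest.fixture(scope="session")
def published_observations(tmp_path_factory) -> list[Observation]:
    """The published example rows parsed through the CSV reader."""
    path = tmp_path_factory.mktemp("fixture") / "published.csv"
    published_frame().to_csv(path, index=False)
    return read_observations(path)
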