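"""Bundled study-level summaries of the four-strain MMS comet study.

These are the published study-level tail-moment means and standard errors
(over at least three independent experiments) for wild-type Oregon-K and the
mus201, mus308 and mus201;mus308 repair-mutant strains treated in vivo with
0, 0.1, 0.5 and 1 mM MMS, together with the measured protein concentrations
of the four strain extracts used in the ex vivo assay.  They serve as inputs
for the dose-response, interaction-factor and worked-example analyses.
"""

from __future__ import annotations

from .records import ConditionSummary

__all__ = [
    "invivo_study_summaries",
    "extract_protein_concentrations",
    "STRAINS",
    "DOSES_MM",
]

STRAINS = ("OK", "mus201", "mus308", "mus201;mus308")
DOSES_MM = (0.0, 0.1, 0.5, 1.0)

# mean TM +/- SE per strain at each dose, n = 3 independent experiments.
_INVIVO = {
    "OK": ((6.20, 0.45), (7.89, 1.12), (9.16, 0.79), (11.13, 1.17)),
    "mus201": ((4.70, 0.57), (8.71, 0.12), (11.42, 0.48), (12.98, 0.58)),
    "mus308": ((3.29, 0.53), (11.76, 1.22), (12.79, 0.55), (17.08, 1.16)),
    "mus201;mus308": ((2.61, 0.14), (14.21, 1.78), (15.28, 0.60), (14.43, 1.42)),
}

# extract protein content, ug/uL (mean of >= 3 aliquot measures).
_PROTEIN = {"OK": 2.49, "mus201": 2.83, "mus308": 2.32, "mus201;mus308": 2.55}


def invivo_study_summaries() -> list[ConditionSummary]:
    """Study-level mean TM +/- SE for every strain x dose cell."""
    return [
        ConditionSummary(
            strain=strain,
            dose=dose,
            extract="none",
            level="study",
            mean_tm=mean,
            se_tm=se,
            n=3,
        )
        for strain, cells in _INVIVO.items()
        for dose, (mean, se) in zip(DOSES_MM, cells)
    ]


def extract_protein_concentrations() -> dict[str, float]:
    """Protein concentration (ug/uL) of each strain extract."""
    return dict(_PROTEIN)
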