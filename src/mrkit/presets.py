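"""Study-regime constants: cohort sizes and instrument strength.

These numbers define the default simulation regime — a serum-protein
exposure measured in a cohort of 997 individuals with seven independent
instruments jointly explaining 12.8% of its variance, analysed against
large binary-outcome GWAS cohorts — and feed the power calculations.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Exposure GWAS sample size (protein-level cohort).
EXPOSURE_N = 997

#: Number of independent instruments in the default regime.
N_INSTRUMENTS = 7

#: Total exposure variance explained by the instrument set.
EXPOSURE_R2_TOTAL = 0.128

#: Bonferroni-corrected significance level for 4 primary tests
#: (2 outcomes x 2 cohorts).
BONFERRONI_ALPHA = 0.0125


@dataclass(frozen=True)
class OutcomeCohort:
    name: str
    outcome: str
    n: int
    cases: int

    @property
    def case_fraction(self) -> float:
        return self.cases / self.n


OUTCOME_COHORTS: dict[str, OutcomeCohort] = {
    "cardiogram_cad": OutcomeCohort("CARDIoGRAMplusC4D", "CAD", 184_305, 60_801),
    "cardiogram_mi": OutcomeCohort("CARDIoGRAMplusC4D", "MI", 184_305, 43_676),
    "finngen_cad": OutcomeCohort("FinnGen", "CAD", 260_405, 25_707),
    "finngen_mi": OutcomeCohort("FinnGen", "MI", 238_338, 15_787),
}
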