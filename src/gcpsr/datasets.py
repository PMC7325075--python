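"""Published reference data for the Esculenta-clade morel survey.

A transcription of the published species x locus conflict-state table for
the twenty-two *Morchella* (Esculenta clade) species scored against four
gene genealogies (the two mating-type genes MAT1-1-1 and MAT1-2-1, the
anonymous locus F1, and the ribosomal intergenic spacer IGS), plus the
published per-locus variable-site counts.  These serve as fixed inputs
for reproducing the survey's headline percentages with this package's
conflict accounting.

State codes: C = conflict (the species' samples are not monophyletic in
that gene genealogy), X = no conflict, O = only one sample amplified,
N = no sample amplified.

Note on the published totals row: the percentages for MAT1-1-1, MAT1-2-1
and IGS follow exactly from the printed states (6/20, 7/20, 13/16); the
printed F1 total (66.7%) does not match a strict tally of the printed F1
column (11 conflicts of 17 evaluable = 64.7%), and the survey's narrative
additionally describes a species-merge in a genealogy whose cell is
printed as no-conflict.  This module transcribes the printed states
verbatim and computes percentages from them; see docs/methods.md.
"""

from __future__ import annotations

from gcpsr.concord import (
    CONFLICT,
    NO_CONFLICT,
    NO_DATA,
    SINGLE_SAMPLE,
    ConflictMatrix,
)

SURVEY_LOCI = ["MAT1-1-1", "MAT1-2-1", "F1", "IGS"]

#: Printed conflict states, one row per species, columns = SURVEY_LOCI.
SURVEY_CONFLICT_STATES: dict[str, str] = {
    "M. americana": "XXXO",
    "M. clivicola": "CXXX",
    "M. dunensis": "XCCC",
    "M. esculenta": "XXCC",
    "M. galilaea": "XXCC",
    "M. palazonii": "XXOC",
    "M. steppicola": "OONN",
    "M. yangii": "CXCC",
    "M. yishuica": "XXXX",
    "Mes-6": "XCCC",
    "Mes-9": "CCCC",
    "Mes-10": "XXOO",
    "Mes-15": "XXXX",
    "Mes-19": "XXCC",
    "Mes-20": "CCCC",
    "Mes-21": "XCCC",
    "Mes-22": "CCXC",
    "Mes-23": "CCCC",
    "Mes-24": "OONN",
    "Mes-25": "XXCO",
    "Mes-26": "XXOC",
    "Mes-27": "XXXO",
}

_CODE_STATE = {"C": CONFLICT, "X": NO_CONFLICT, "O": SINGLE_SAMPLE, "N": NO_DATA}

#: Published per-locus variable-site counts: locus -> (n_variable, n_sites).
SURVEY_VARIABLE_SITES = {
    "MAT1-1-1": (120, 654),
    "MAT1-2-1": (158, 827),
}

#: Published all-sample nucleotide diversity per mating-type locus.
SURVEY_PI = {"MAT1-1-1": 0.0177, "MAT1-2-1": 0.0237}


def survey_conflict_matrix() -> ConflictMatrix:
    """The transcribed published state table as a ConflictMatrix."""
    states = {
        (sp, locus): _CODE_STATE[row[i]]
        for sp, row in SURVEY_CONFLICT_STATES.items()
        for i, locus in enumerate(SURVEY_LOCI)
    }
    return ConflictMatrix(list(SURVEY_CONFLICT_STATES), list(SURVEY_LOCI), states)
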