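"""Synthetic name pools for the cohort simulator.

All names are synthetic/common-word combinations; no real person data.
Suffix pool includes Roman-numeral generational suffixes so that the
name-QC rules (which must NOT flag Roman numerals) are exercised.
"""

SURNAMES = [
    "ADLER", "BAKER", "BARNES", "BECKER", "BENNETT", "BLAKE", "BOWMAN",
    "BRENNAN", "CARTER", "CHAVEZ", "CLARKE", "COLEMAN", "CRUZ", "DALTON",
    "DAWSON", "DELGADO", "DONOVAN", "DUFFY", "ELLIS", "FARRELL", "FISHER",
    "FLEMING", "FOSTER", "GARNER", "GIBSON", "GRADY", "GRIFFIN", "HAINES",
    "HARMON", "HOLDEN", "HUBBARD", "INGRAM", "JENSEN", "KEATING", "KELLER",
    "LANDRY", "LAWSON", "MARSH", "MCBRIDE", "MERCER", "MONROE", "NAVARRO",
    "NOLAN", "OSBORNE", "PARRISH", "QUINN", "RAMSEY", "REDMOND", "SAWYER",
    "SHEPARD", "SLOAN", "TALBOT", "THORNE", "VANCE", "WALSH", "WEBSTER",
    "WHITFIELD", "YATES", "ZIMMER", "O'BRIEN", "SMITH-JONES",
]

GIVEN_NAMES = [
    "ALICE", "ARTHUR", "BEATRICE", "BERNARD", "CELIA", "CHARLES", "DAPHNE",
    "DOUGLAS", "ELEANOR", "EDWIN", "FIONA", "FRANK", "GRETA", "GORDON",
    "HELENA", "HAROLD", "IRENE", "ISAAC", "JUDITH", "JASPER", "KATHRYN",
    "KENNETH", "LUCILLE", "LEONARD", "MIRIAM", "MARTIN", "NADIA", "NELSON",
    "OPHELIA", "OSCAR", "PAULINE", "PATRICK", "QUINCY", "ROSALIND", "RUSSELL",
    "SYLVIA", "STANLEY", "THEODORA", "TOBIAS", "URSULA", "VICTOR", "WILMA",
    "WALLACE", "XENIA", "YVONNE", "ZACHARY",
]

MIDDLE_INITIALS = list("ABCDEFGHJKLMNPRSTVW")

# Generational suffixes; Roman numerals on purpose (must survive name QC).
SUFFIXES = ["JR", "SR", "II", "III", "IV"]
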