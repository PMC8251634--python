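"""Published per-replicate duplex-sequencing counts used as inputs.

The 18-sample table of total duplex bases sequenced and mutant
nucleotides detected across a 28-day EMS concentration series (vehicle
control plus 6.25, 25, 50 and 100 ug/mL) drives the arithmetic and
statistics layers without any sequencing re-run. Base counts are as
printed, in units of 1e6 bases; printed mutant frequencies (x1e-7) are
retained for cross-checking since two cells reflect rounding of the
underlying base counts.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # concentration (ug/mL), replicate, duplex bases (x1e6), mutants, printed MF (x1e-7)
    (0.0, 1, 481, 76, 1.58),
    (0.0, 2, 513, 75, 1.46),
    (0.0, 3, 636, 156, 2.45),
    (0.0, 4, 727, 131, 1.80),
    (6.25, 1, 796, 189, 2.37),
    (6.25, 2, 323, 64, 1.98),
    (6.25, 3, 709, 174, 2.45),
    (25.0, 1, 699, 220, 3.15),
    (25.0, 2, 726, 244, 3.36),
    (25.0, 3, 725, 205, 2.83),
    (50.0, 1, 444, 161, 3.62),
    (50.0, 2, 456, 172, 3.77),
    (50.0, 3, 685, 300, 4.38),
    (50.0, 4, 642, 280, 4.36),
    (100.0, 1, 423, 423, 10.00),
    (100.0, 2, 398, 325, 8.17),
    (100.0, 3, 746, 875, 11.73),
    (100.0, 4, 407, 458, 11.24),
]

#: Mean %DNA in Tail per concentration reported for the 3-day and 28-day
#: comet series; used to parameterize the synthetic comet generator.
COMET_MEAN_PERCENT_TAIL = {
    "day3": {0.0: 3.8, 6.25: 10.2, 25.0: 28.7, 50.0: 58.5, 100.0: 83.3},
    "day28": {0.0: 6.7, 6.25: 33.5, 25.0: 78.5, 50.0: 87.0, 100.0: 87.2},
}


def duplex_study_table() -> pd.DataFrame:
    """Per-replicate duplex sequencing counts of the 28-day study.

    Columns: concentration (ug/mL, 0 = vehicle control), replicate,
    duplex_bases (absolute base count), mutants, printed_mf
    (x1e-7 scale, as published).
    """
    df = pd.DataFrame(
        _ROWS,
        columns=["concentration", "replicate", "duplex_bases_e6",
                 "mutants", "printed_mf"],
    )
    df["duplex_bases"] = (df["duplex_bases_e6"] * 1_000_000).astype("int64")
    return df


def mutant_frequency_endpoints() -> pd.DataFrame:
    """Replicate mutant frequencies (x1e-7) as an endpoint table for the
    dose-response layer, recomputed from the printed counts."""
    df = duplex_study_table()
    out = pd.DataFrame({
        "sample_id": [
            f"c{int(c)}r{r}" for c, r in zip(df["concentration"], df["replicate"])
        ],
        "concentration": df["concentration"],
        "replicate": df["replicate"],
        "value": df["mutants"] / df["duplex_bases"] * 1e7,
    })
    return out
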