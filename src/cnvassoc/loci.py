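"""Candidate CNV loci previously implicated in schizophrenia.

Fifteen rare large CNV loci with a priori case-enrichment hypotheses,
coordinates in bp on UCSC build hg18. ``REPORTED_EA_FREQUENCIES`` carries
the carrier frequencies reported for these loci in a large European-
ancestry case-control cohort (2416 SZ cases, 2393 healthy controls); they
serve as reference inputs for reconstructing the published carrier counts
(count = round(frequency x group size)). A locus reported without
frequencies was not captured on the source platform.
"""

from __future__ import annotations

from .types import ImplicatedLocus, State, Tail

EA_N_SZ = 2416
EA_N_HC = 2393
EA_N_BD = 592

IMPLICATED_SZ_LOCI: list[ImplicatedLocus] = [
    ImplicatedLocus("1q21.1 dup", "1", 144_643_825, 146_395_960, State.DUPLICATION, Tail.ONE),
    ImplicatedLocus("1q21.1 del", "1", 144_643_825, 146_395_960, State.DELETION, Tail.ONE),
    ImplicatedLocus("NRXN1 del", "2", 50_429_732, 51_543_819, State.DELETION, Tail.ONE),
    ImplicatedLocus("3q29 del", "3", 197_190_376, 198_838_385, State.DELETION, Tail.ONE),
    ImplicatedLocus("WBS dup", "7", 72_297_543, 73_780_040, State.DUPLICATION, Tail.ONE),
    ImplicatedLocus("VIPR2 dup", "7", 158_137_395, 158_819_765, State.DUPLICATION, Tail.ONE),
    ImplicatedLocus("15q11.2 del", "15", 20_302_458, 20_852_214, State.DELETION, Tail.ONE),
    ImplicatedLocus("AS/PWS dup", "15", 20_224_763, 26_742_083, State.DUPLICATION, Tail.ONE),
    ImplicatedLocus("15q13.3 del", "15", 28_173_703, 30_664_276, State.DELETION, Tail.ONE),
    ImplicatedLocus("16p13.11 dup", "16", 15_306_385, 16_588_399, State.DUPLICATION, Tail.ONE),
    ImplicatedLocus("16p11.2 del", "16", 29_158_416, 30_134_444, State.DELETION, Tail.ONE),
    ImplicatedLocus("16p11.2 dup", "16", 29_158_416, 30_134_444, State.DUPLICATION, Tail.ONE),
    ImplicatedLocus("17p12 del", "17", 14_023_683, 15_425_596, State.DELETION, Tail.ONE),
    ImplicatedLocus("17q12 del", "17", 31_610_407, 33_552_901, State.DELETION, Tail.ONE),
    ImplicatedLocus("22q11.2 del", "22", 17_028_880, 20_058_138, State.DELETION, Tail.ONE),
]

# locus name -> (control carrier frequency, SZ carrier frequency);
# None: the locus was not captured in the reference cohort.
REPORTED_EA_FREQUENCIES: dict[str, tuple[float, float] | None] = {
    "1q21.1 dup": (0.00000, 0.00210),
    "1q21.1 del": (0.00042, 0.00083),
    "NRXN1 del": (0.00000, 0.00083),
    "3q29 del": (0.00000, 0.00166),
    "WBS dup": (0.00000, 0.00124),
    "VIPR2 dup": (0.00042, 0.00083),
    "15q11.2 del": (0.00084, 0.00124),
    "AS/PWS dup": (0.00000, 0.00041),
    "15q13.3 del": (0.00042, 0.00290),
    "16p13.11 dup": (0.00042, 0.00000),
    "16p11.2 del": None,
    "16p11.2 dup": (0.00000, 0.00373),
    "17p12 del": (0.00042, 0.00000),
    "17q12 del": (0.00000, 0.00041),
    "22q11.2 del": (0.00000, 0.00662),
}


def reconstruct_counts(name: str) -> tuple[int, int] | None:
    """(SZ carriers, HC carriers) reconstructed from reported frequencies."""
    freqs = REPORTED_EA_FREQUENCIES.get(name)
    if freqs is None:
        return None
    hc_freq, sz_freq = freqs
    return round(sz_freq * EA_N_SZ), round(hc_freq * EA_N_HC)
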