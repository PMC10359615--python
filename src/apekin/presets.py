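"""Published reference parameters used as simulation truths and report inputs.

These are the measured kinetic, binding, FRET and mass-photometry
quantities for human APE1 acting on abasic-site substrates that mimic a
stalled replication fork: canonical duplex DNA (``dsDNA``), a
primer-template junction with the abasic site at the junction (``PTJ``),
a recessed junction with the site 7 nt into the single-stranded overhang
(``Rec-PTJ``), and free single-stranded DNA (``ssDNA``).  Multiple-
turnover entries are (kobs, se_kobs, kss, se_kss) in s^-1 at the standard
design (DNA 100 nM, enzyme 30 nM); the burst amplitude is taken as the
full enzyme concentration when reconstructing truth curves, so
vss = kss * 30 nM.
"""

from __future__ import annotations

from .models import KineticParams

# substrate -> (kobs, se_kobs, kss, se_kss), wild-type enzyme, multiple turnover
MT_WT = {
    "dsDNA": (129.0, 24.0, 1.7, 0.26),
    "PTJ": (10.0, 1.0, 2.7, 0.21),
    "Rec-PTJ": (30.0, 4.0, 5.9, 0.32),
    "ssDNA": (2.0, 0.2, 0.15, 0.018),
}

# substrate -> (kobs, se_kobs, kss, se_kss), R177A mutant, multiple turnover
MT_R177A = {
    "PTJ": (0.23, 0.03, 0.07, 0.003),
    "Rec-PTJ": (0.12, 0.015, 0.06, 0.006),
    "ssDNA": (0.001, 0.0001, 0.0001, 0.000008),
}

# substrate -> (kobs, se), wild-type single turnover (single exponential)
ST_WT = {
    "PTJ": (13.6, 0.4),
    "Rec-PTJ": (25.7, 1.6),
}

# substrate -> (major-population rate, se), R177A single turnover (double exp)
ST_R177A_MAJOR = {
    "PTJ": (0.05, 0.004),
    "Rec-PTJ": (0.06, 0.006),
}

# substrate -> (KD_app nM, se), EMSA tight-binding fits at 5 nM DNA
KD_APP = {
    "dsDNA": (0.4, 0.1),
    "PTJ": (1.2, 0.1),
    "Rec-PTJ": (0.7, 0.05),
    "ssDNA": (22.0, 3.0),
}

# FRET exchange anchors: substrate -> (E_FRET high, sem, E_FRET low, sem)
FRET_ANCHORS = {
    "Rec-PTJ": (0.475, 0.0227, 0.204, 0.00394),
    "PTJ": (0.524, 0.00608, 0.205, 0.00538),
}

# observed 50%-inhibition ratios [Competitor]/[DNA]_Total
COMPETITION_MIDPOINT = {
    "Rec-PTJ self": (0.487, 0.00561),
    "PTJ competitor": (0.413, 0.0447),
}

# DNA:RPA stoichiometry populations on the 30-nt-overhang junction at 3:1 RPA:DNA
RPA_POPULATIONS = {"1-RPA": 0.90, "2-RPA": 0.10}

# generator defaults for the mass mixture: component means (kDa) for the
# 1-RPA and 2-RPA complexes (RPA ~116 kDa on a ~34 kDa junction DNA) and a
# typical mass-photometry peak width
RPA_MASS_MEANS_KDA = (150.0, 266.0)
RPA_MASS_SIGMA_KDA = 12.0

ENZYME_TOTAL_NM = 30.0  # multiple-turnover enzyme concentration


def mt_truth(substrate: str, enzyme: str = "WT") -> KineticParams:
    """Multiple-turnover truth curve parameters for a published substrate.

    The burst amplitude is set to the total enzyme concentration (30 nM)
    and vss follows from the published kss, so the reconstructed curve
    reproduces the published rate constants exactly.
    """
    table = MT_WT if enzyme == "WT" else MT_R177A
    kobs, se_kobs, kss, se_kss = table[substrate]
    A = ENZYME_TOTAL_NM
    return KineticParams(A=A, kobs=kobs, vss=kss * A,
                         se_kobs=se_kobs, se_kss=se_kss)
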