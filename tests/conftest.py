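"""Shared fixtures: reference annotation, printed-table expectations, and a
session-scoped synthetic genome."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import mitochar as mc

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


# Printed characterization-table expectations for the reference pangolin
# mitogenome: gene -> (printed length, intergenic, strand).  The control
# region (D_loop) prints length 1049 although its coordinates span 1050 bp;
# it is listed here with the printed value and handled separately in tests.
PRINTED_TABLE1: dict[str, tuple[int, int, str]] = {
    "tRNA-Phe": (68, 0, "H"),
    "12S ribosomal RNA": (960, 0, "H"),
    "tRNA-Val": (66, -1, "H"),
    "16S ribosomal RNA": (1566, 0, "H"),
    "tRNA-Leu(UAA)": (74, 0, "H"),
    "ND1": (957, 3, "H"),
    "tRNA-Ile": (69, -1, "H"),
    "tRNA-Gln": (73, -3, "L"),
    "tRNA-Met": (69, 1, "H"),
    "ND2": (1039, -27, "H"),
    "tRNA-Trp": (67, 27, "H"),
    "tRNA-Ala": (69, 3, "L"),
    "tRNA-Asn": (73, 1, "L"),
    "tRNA-Cys": (65, 32, "L"),
    "tRNA-Tyr": (67, 0, "L"),
    "COX1": (1551, 1, "H"),
    "tRNA-Ser(UGA)": (69, -5, "L"),
    "tRNA-Asp": (67, 7, "H"),
    "COX2": (684, 0, "H"),
    "tRNA-Lys": (64, 2, "H"),
    "ATP8": (201, 1, "H"),
    "ATP6": (681, -40, "H"),
    "COX3": (784, -1, "H"),
    "tRNA-Gly": (69, 0, "H"),
    "ND3": (347, 0, "H"),
    "tRNA-Arg": (67, 0, "H"),
    "ND4L": (297, 0, "H"),
    "ND4": (1378, -7, "H"),
    "tRNA-His": (68, 0, "H"),
    "tRNA-Ser(GCU)": (59, 0, "H"),
    "tRNA-Leu(UAG)": (71, 1, "H"),
    "ND5": (1812, 9, "H"),
    "ND6": (525, -17, "L"),
    "tRNA-Glu": (69, 0, "L"),
    "CYTB": (1140, 3, "H"),
    "tRNA-Thr": (67, 0, "H"),
    "tRNA-Pro": (67, -1, "L"),
    "D_loop": (1049, 113, "H"),
}

PRINTED_STARTS_STOPS: dict[str, tuple[str, str]] = {
    "ND1": ("ATG", "TAA"), "ND2": ("ATG", "T--"), "COX1": ("ATG", "AGA"),
    "COX2": ("ATG", "TAA"), "ATP8": ("ATG", "TAA"), "ATP6": ("ATG", "TAA"),
    "COX3": ("ATG", "T--"), "ND3": ("ATA", "TA-"), "ND4L": ("ATG", "TAA"),
    "ND4": ("ATG", "T--"), "ND5": ("ATA", "TAA"), "ND6": ("ATG", "AGA"),
    "CYTB": ("ATG", "AGA"),
}

# Printed composition-table rows: region -> (A%, C%, G%, T%, AT skew, GC skew)
PRINTED_TABLE2: dict[str, tuple[float, float, float, float, float, float]] = {
    "ribosomal RNA": (37.92, 21.54, 17.74, 22.80, 0.2490, -0.0967),
    "12S ribosomal RNA": (36.87, 22.92, 17.92, 22.29, 0.2465, -0.1224),
    "16S ribosomal RNA": (38.57, 20.69, 17.62, 23.12, 0.2504, -0.0801),
    "protein-coding genes": (31.84, 29.35, 13.28, 25.53, 0.1100, -0.3770),
    "ND1": (33.02, 29.99, 12.23, 24.76, 0.1430, -0.4207),
    "ND2": (37.63, 30.80, 9.14, 22.43, 0.2531, -0.5423),
    "COX1": (28.43, 27.21, 15.51, 27.85, 0.0103, -0.2739),
    "COX2": (32.16, 28.95, 13.74, 25.15, 0.1223, -0.3563),
    "ATP8": (38.81, 29.85, 7.46, 23.88, 0.2382, -0.6001),
    "ATP6": (33.33, 32.89, 10.72, 23.06, 0.1821, -0.5084),
    "COX3": (26.79, 30.99, 16.33, 25.89, 0.0171, -0.3098),
    "ND3": (34.29, 31.70, 10.95, 23.06, 0.1958, -0.4865),
    "ND4L": (31.98, 29.97, 11.45, 26.60, 0.0918, -0.4471),
    "ND4": (33.67, 31.57, 11.25, 23.51, 0.1777, -0.4745),
    "ND5": (34.93, 30.41, 9.88, 24.78, 0.1700, -0.5096),
    "ND6": (16.38, 8.57, 32.57, 42.48, -0.4434, 0.5834),
    "transfer RNA": (36.46, 20.94, 15.38, 27.22, 0.1451, -0.1531),
}


@pytest.fixture(scope="session")
def ref_features():
    return mc.reference_features()


@pytest.fixture(scope="session")
def default_tpl():
    return mc.default_template()


@pytest.fixture(scope="session")
def synthetic_genome(default_tpl):
    genome, truth = mc.generate_mitogenome(default_tpl, seed=1)
    return genome, truth
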