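"""Small built-in datasets for examples and reproducibility checks."""

from __future__ import annotations

from .qc import QCRecord

__all__ = ["rhizobiales_flagged_qc", "RHIZOBIALES_TYPE_STRAIN_COUNT"]

#: number of Rhizobiales type-strain genome assemblies in the published
#: survey this QC table comes from
RHIZOBIALES_TYPE_STRAIN_COUNT = 520

_ROWS = [
    # accession, organism, length_mb, contigs, completeness, redundancy
    ("GCF_000421945.1", "Agrobacterium radiobacter DSM 30147^T^", 7.18, 612, 0.7077, 1.6195),
    ("GCF_001187535.1", "Rhizobium ecuadorense CNPSO 671^T^", 7.38, 1891, 0.9813, 1.1221),
    ("GCF_001641635.1", "Bradyrhizobium centrolobii BR 10245^T^", 10.11, 133, 0.9814, 1.1206),
    ("GCF_001723295.1", "Methyloceanibacter marginalis R-67177^T^", 3.00, 470, 0.8782, 1.0293),
    ("GCF_001723305.1", "Methyloceanibacter superfactus R-67175^T^", 3.10, 38, 0.8961, 1.0245),
    ("GCF_002759055.1", "Methylobacterium frigidaeris IER25-16^T^", 6.40, 1670, 0.893, 1.0415),
    ("GCF_002866925.1", "Cohaesibacter celericrescens H1304^T^", 5.02, 59, 0.9684, 1.1036),
    ("GCF_002930635.1", "Kaistia algarum LYH11^T^", 6.21, 598, 0.9814, 1.1927),
    ("GCF_003024595.1", "Mesorhizobium plurifarium LMG 11892^T^", 4.42, 35, 1.0, 1.1446),
    ("GCF_003024615.1", "Mesorhizobium loti LMG 6125^T^", 4.88, 52, 0.9979, 1.1806),
    ("GCF_003049685.1", "Ochrobactrum pituitosum CCUG 50899^T^", 5.52, 10, 0.9814, 1.1275),
    ("GCF_902162175.1", "Bartonella saheliensis 077^T^", 2.26, 131, 0.8198, 1.1681),
]


def rhizobiales_flagged_qc() -> list[QCRecord]:
    """Published QC metrics for the 12 Rhizobiales type-strain assemblies
    that failed the completeness <= 0.9 / redundancy >= 1.1 screen in a
    520-genome survey of the order.

    Useful as a worked example for :func:`genoclust.qc.qc_flag`: every row
    trips at least one of the default thresholds.
    """
    return [QCRecord(*row) for row in _ROWS]
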