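"""The published endometrial-cancer verification panel.

The verification study monitored 52 candidate proteins (98 light/heavy
peptide pairs) in uterine aspirates from 20 tumor and 18 control
patients; 48 peptides from 26 proteins passed the significance gate
(BH-adjusted p < 0.05 and fold change > 3). The table below transcribes
those 48 rows — fold change, adjusted p, per-group interquartile ranges
of the light/heavy ratio, AUC and the reported operating points — and
is the stated world from which the cohort generator draws its group
distributions.

Quartiles printed as "0.00" are values censored at the table's
two-decimal precision; :data:`MIN_QUARTILE` (half the last printed
digit) substitutes for them so a positive log-normal can be fitted.
"""

from __future__ import annotations

from .simulate import PeptideSpec

__all__ = ["VERIFIED_PANEL", "MIN_QUARTILE", "published_peptide_specs", "default_panel"]

MIN_QUARTILE = 0.005

# protein, peptide, FC, adj p, tumor Q1, tumor Q3, control Q1, control Q3,
# AUC, sensitivity %, specificity %, sensitivity % at 95% specificity
VERIFIED_PANEL: list[tuple] = [
    ("PERM", "IANVFTNAFR", 14.1, 6e-5, 0.56, 2.18, 0.04, 0.13, 0.97, 95, 89, 80),
    ("PERM", "VVLEGGIDPILR", 13.3, 1e-4, 0.94, 4.00, 0.08, 0.29, 0.95, 95, 89, 70),
    ("CADH1", "VFYSITGQGADTPPVGVFIIER", 3.8, 9e-5, 0.55, 1.27, 0.11, 0.28, 0.94, 95, 89, 85),
    ("CADH1", "NLVQIK", 3.3, 2e-4, 0.44, 1.09, 0.12, 0.25, 0.93, 85, 94, 85),
    ("SPIT1", "SFVYGGCLGNK", 3.3, 1e-4, 0.33, 0.66, 0.07, 0.20, 0.93, 95, 94, 95),
    ("SPIT1", "WYYDPTEQICK", 3.3, 1e-4, 0.30, 0.55, 0.06, 0.18, 0.93, 90, 94, 90),
    ("ENOA", "YISPDQLADLYK", 3.8, 1e-4, 13.43, 25.66, 2.89, 5.76, 0.92, 75, 94, 75),
    ("ENOA", "TIAPALVSK", 4.0, 2e-4, 6.85, 18.62, 1.51, 3.23, 0.89, 80, 83, 70),
    ("MMP9", "SLGPALLLLQK", 5.7, 1e-4, 0.52, 2.42, 0.05, 0.19, 0.91, 95, 83, 60),
    ("MMP9", "AFALWSAVTPLTFTR", 5.5, 1e-4, 0.35, 1.60, 0.03, 0.14, 0.91, 90, 83, 60),
    ("LDHA", "LVIITAGAR", 6.2, 1e-4, 3.55, 7.23, 0.26, 0.78, 0.91, 85, 89, 65),
    ("LDHA", "VTLTSEEEAR", 5.7, 1e-4, 11.32, 22.52, 0.94, 2.75, 0.91, 85, 89, 60),
    ("CASP3", "SGTDVDAANLR", 4.9, 2e-4, 0.04, 0.11, 0.00, 0.02, 0.91, 90, 89, 65),
    ("KPYM", "NTGIICTIGPASR", 5.4, 1e-4, 10.82, 41.42, 1.29, 5.52, 0.91, 85, 89, 75),
    ("KPYM", "APIIAVTR", 3.1, 1e-2, 0.43, 1.39, 0.10, 0.51, 0.75, 60, 89, 50),
    ("PRDX1", "LVQAFQFTDK", 4.2, 2e-4, 11.08, 27.24, 2.06, 7.32, 0.90, 75, 94, 75),
    ("PRDX1", "ADEGISFR", 4.2, 2e-4, 0.80, 1.93, 0.16, 0.52, 0.90, 75, 94, 75),
    ("OSTP", "ANDESNEHSDVIDSQELSK", 11.4, 2e-4, 0.11, 0.44, 0.00, 0.05, 0.90, 80, 94, 80),
    ("OSTP", "AIPVAQDLNAPSDWDSR", 9.0, 4e-4, 0.10, 0.56, 0.01, 0.07, 0.87, 80, 83, 50),
    ("PDIA1", "ILEFFGLK", 3.3, 3e-4, 0.16, 0.41, 0.03, 0.13, 0.89, 75, 89, 65),
    ("PDIA1", "ALAPEYAK", 3.0, 3e-4, 0.26, 0.65, 0.06, 0.22, 0.88, 75, 89, 65),
    ("NAMPT", "YLLETSGNLDGLEYK", 4.2, 3e-4, 0.31, 1.04, 0.01, 0.16, 0.88, 90, 83, 40),
    ("NAMPT", "YDGHLPIEIK", 4.0, 3e-4, 0.57, 2.05, 0.08, 0.32, 0.88, 90, 83, 40),
    ("MIF", "VYINYYDMNAANVGWNNSTFA", 4.2, 3e-4, 0.91, 1.89, 0.05, 0.45, 0.88, 75, 94, 75),
    ("MIF", "LLCGLLAER", 3.1, 3e-4, 45.14, 98.96, 11.49, 27.40, 0.87, 70, 94, 70),
    ("CTNB1", "LLNDEDQVVVNK", 4.2, 3e-4, 0.06, 0.21, 0.00, 0.04, 0.88, 85, 89, 70),
    ("CTNB1", "LVQLLVR", 4.2, 3e-4, 0.07, 0.27, 0.00, 0.04, 0.87, 85, 89, 65),
    ("K2C8", "LSELEAALQR", 3.6, 3e-4, 1.04, 2.99, 0.17, 0.92, 0.88, 95, 67, 65),
    ("K2C8", "WSLLQQQK", 3.1, 6e-4, 0.45, 1.25, 0.09, 0.45, 0.85, 60, 94, 60),
    ("ANXA2", "GVDEVTIVNILTNR", 4.8, 4e-4, 5.60, 20.24, 1.36, 4.74, 0.87, 75, 89, 45),
    ("ANXA2", "QDIAFAYQR", 5.1, 5e-4, 0.26, 1.07, 0.05, 0.25, 0.86, 95, 61, 50),
    ("CAPG", "EGNPEEDLTADK", 3.6, 5e-4, 0.32, 1.11, 0.05, 0.17, 0.85, 85, 83, 45),
    ("CAPG", "YQEGGVESAFHK", 3.5, 6e-4, 0.44, 1.63, 0.08, 0.27, 0.85, 80, 83, 45),
    ("FABP5", "LVVECVMNNVTCTR", 3.9, 6e-4, 2.27, 8.29, 0.84, 1.56, 0.85, 90, 78, 45),
    ("FABP5", "ELGVGIALR", 3.6, 6e-4, 0.03, 0.10, 0.01, 0.02, 0.85, 90, 78, 45),
    ("MUC1", "QGGFLGLSNIK", 3.6, 1e-3, 5.11, 12.65, 1.18, 4.04, 0.84, 85, 78, 45),
    ("CAYP1", "SGDGVVTVDDLR", 3.4, 1e-3, 4.04, 19.35, 1.16, 3.48, 0.83, 85, 78, 45),
    ("XPO2", "ANIVHLMLSSPEQIQK", 4.0, 1e-3, 0.05, 0.19, 0.00, 0.04, 0.83, 75, 89, 25),
    ("XPO2", "LLQTDDEEEAGLLELLK", 4.4, 2e-3, 0.04, 0.22, 0.00, 0.04, 0.81, 70, 89, 40),
    ("NGAL", "VPLQQNFQDNQFQGK", 5.0, 1e-3, 2.19, 8.19, 0.29, 2.03, 0.83, 75, 89, 35),
    ("NGAL", "ELTSELK", 4.4, 4e-3, 2.09, 9.13, 0.35, 2.04, 0.79, 70, 83, 30),
    ("SG2A1", "ELLQEFIDSDAAAEAMGK", 3.3, 3e-3, 0.15, 0.35, 0.02, 0.17, 0.80, 90, 72, 30),
    ("SG2A1", "TINSDISIPEYK", 3.2, 5e-3, 0.12, 0.30, 0.02, 0.14, 0.78, 90, 67, 40),
    ("ANXA1", "DITSDTSGDFR", 4.8, 3e-3, 1.12, 4.44, 0.33, 1.16, 0.80, 60, 100, 60),
    ("ANXA1", "GGPGSAVSPYPTFNPSSDVAALHK", 3.9, 7e-3, 1.33, 6.02, 0.51, 2.02, 0.77, 55, 100, 55),
    ("HSPB1", "LFDQAFGLPR", 3.6, 4e-3, 1.31, 7.31, 0.60, 1.78, 0.79, 85, 67, 40),
    ("HSPB1", "LATQSNEITIPVTFESR", 3.1, 4e-3, 2.74, 13.66, 1.27, 3.67, 0.79, 85, 67, 40),
    ("PIGR", "VYTVDLGR", 3.4, 7e-3, 38.67, 128.80, 15.43, 37.38, 0.77, 80, 78, 30),
]

# Column indices for readers of VERIFIED_PANEL rows.
COL_PROTEIN, COL_PEPTIDE, COL_FC, COL_ADJ_P = 0, 1, 2, 3
COL_TQ1, COL_TQ3, COL_CQ1, COL_CQ3 = 4, 5, 6, 7
COL_AUC, COL_SENS, COL_SPEC, COL_SENS95 = 8, 9, 10, 11


def published_quartiles(peptide: str) -> tuple[float, float, float, float]:
    """(tumor Q1, tumor Q3, control Q1, control Q3) for a panel peptide,
    with censored zeros lifted to MIN_QUARTILE."""
    for row in VERIFIED_PANEL:
        if row[COL_PEPTIDE] == peptide:
            return tuple(max(q, MIN_QUARTILE) for q in row[COL_TQ1:COL_CQ3 + 1])
    raise KeyError(f"peptide {peptide!r} not in the verified panel")


def published_auc(peptide: str) -> float:
    for row in VERIFIED_PANEL:
        if row[COL_PEPTIDE] == peptide:
            return float(row[COL_AUC])
    raise KeyError(f"peptide {peptide!r} not in the verified panel")


def published_peptide_specs() -> list[PeptideSpec]:
    """The 48 significant peptides as generator specs."""
    specs = []
    for row in VERIFIED_PANEL:
        tq1, tq3, cq1, cq3 = (max(q, MIN_QUARTILE) for q in row[COL_TQ1:COL_CQ3 + 1])
        specs.append(
            PeptideSpec(
                protein=row[COL_PROTEIN], peptide=row[COL_PEPTIDE],
                tumor_q1=tq1, tumor_q3=tq3, control_q1=cq1, control_q3=cq3,
            )
        )
    return specs


# Monitored peptides that sat below the limit of detection in most
# samples and were removed from the verification study by the >50% rule.
BELOW_LOD_PEPTIDES = ("VHITSLLPTPEDNLEIVLHR", "VTILELFR")


def default_panel() -> list[PeptideSpec]:
    """The full monitored panel the generator emulates: 52 proteins and
    100 peptide pairs — the 48 published differential peptides, 50
    non-differential filler peptides whose tumor and control
    distributions coincide (standing in for the candidates that did not
    pass the gate), and the two undetectable peptides that the LOD rule
    removed in the study, leaving 98 testable pairs. 46 proteins carry
    two detectable peptides, matching the sibling-correlation
    denominator of the study.
    """
    specs = published_peptide_specs()
    n_filler_proteins = 26
    k = 0
    for i in range(n_filler_proteins):
        # log-spread the baseline abundances across the panel's dynamic range
        base = 0.05 * (10 ** (2.5 * i / (n_filler_proteins - 1)))
        n_peptides = 2 if i < n_filler_proteins - 2 else 1  # 24x2 + 2x1 = 50
        for _ in range(n_peptides):
            k += 1
            specs.append(
                PeptideSpec(
                    protein=f"NDF{i + 1:02d}",
                    peptide=f"NONDIFFPEP{k:02d}",
                    tumor_q1=0.6 * base, tumor_q3=1.6 * base,
                    control_q1=0.6 * base, control_q3=1.6 * base,
                )
            )
    # the two below-LOD peptides ride on the single-peptide filler proteins
    for j, peptide in enumerate(BELOW_LOD_PEPTIDES):
        specs.append(
            PeptideSpec(
                protein=f"NDF{n_filler_proteins - 1 + j:02d}",
                peptide=peptide,
                tumor_q1=0.6, tumor_q3=1.6,
                control_q1=0.6, control_q3=1.6,
                detectable=False,
            )
        )
    return specs
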