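"""Curated reference gene lists for the deterministic fixture.

Phase-labelled transcription-factor symbols from ST2 stromal-cell
osteoblast differentiation profiling (five temporal phases, 110 symbols
in chronological cluster order) and the eleven bHLH-superfamily members
with their per-lineage behavior (arrows) and peak-regulation cluster
labels on both the osteoblast and adipocyte courses. Symbols are kept
exactly as curated (including Fabp4, a non-TF symbol listed in phase 3).
"""
from __future__ import annotations

#: Osteoblast phase label -> up-regulated TF symbols, chronological order.
OSTEOBLAST_PHASE_GENES: dict[str, tuple[str, ...]] = {
    "1hr": (
        "Foxc2", "Nfatc1", "Hoxb2", "Fkhl18", "Med14", "Id4", "Msx2", "Id2",
        "Ankrd1", "Hes1", "Bhlhe40", "Foxn1", "Tle4", "Hmga2", "Dlx3",
        "Gata2", "Dlx2", "Nr4a3", "Axud1", "Eaf1", "Hipk2", "AC153948.5",
        "Zfx", "Cebpb", "Grhl1", "Smad7", "Rel", "Maff", "Mafk", "Klf16",
        "Id1", "Nfil3", "Fosl1", "Klf5", "Npas4", "Lmcd1", "Atf3", "Fosb",
        "Mef2c", "Erf", "Mef2a", "Atp6v0a1", "Srf", "Tgif1", "Nr4a1", "Junb",
    ),
    "6-24hr": (
        "Hey1", "Atoh8", "Helb", "Hdac9", "Atf6", "Gcom1", "Hoxa1", "Prrx1",
        "Tgfb1", "Creb3l1", "Rbm9", "Elk3", "C1d", "Dlx1", "Pde8a", "Hey2",
        "Ets2", "Dtna", "Smad6", "Foxo1", "Cux1", "Gatad2b", "Irf5", "Rfc1",
        "Sp7", "Arnt2", "Aebp1", "Hoxc13", "Aff3",
    ),
    "30-48hr": ("Lef1", "Fabp4", "Stat5a", "Prrx2"),
    "4-6d": ("Hod", "Maf", "Foxf2", "Sox9", "Stat1", "Foxd1", "Neo1"),
    "8-14d": (
        "Stat2", "Esr1", "Klf9", "Klf13", "AC162313.5", "Cml3", "Pou6f1",
        "Pura", "Nfat5", "Zfp521", "Trib3", "Ddit3", "2210012G02Rik",
        "Clock", "Irf7", "Nr3c1", "Irf9", "Zhx2", "Sqstm1", "Znfx1", "Atf5",
        "Hoxa9", "Nr1d2", "Nfe2l1",
    ),
}

#: The eleven bHLH superfamily members:
#: symbol -> (osteoblast behavior, adipocyte behavior,
#:            osteoblast cluster label, adipocyte cluster label or None).
BHLH_GENES: dict[str, tuple[str, str, str, str | None]] = {
    "Bhlhe40": ("UP", "DOWN", "1hr", "4d"),
    "Hes1": ("UP", "DOWN", "1hr", "4d"),
    "Id1": ("UP_DOWN", "DOWN", "1hr", "10-14d"),
    "Id2": ("UP_DOWN", "DOWN", "1hr", "2d"),
    "Id4": ("UP", "DOWN", "1hr", "4d"),
    "Npas4": ("UP_DOWN", "DOWN", "1hr", "2d"),
    "Arnt2": ("UP", "UNCHANGED", "6-24hr", None),
    "Atoh8": ("UP_DOWN", "DOWN", "6-24hr", "2d"),
    "Hey1": ("UP", "UNCHANGED", "6-24hr", None),
    "Hey2": ("UP", "UNCHANGED", "6-24hr", None),
    "Clock": ("UP", "UP", "8-14d", "10-14d"),
}

#: Lineage-switch candidates: two-fold or greater up-regulated in the
#: osteoblast course and one-half fold or lower in the adipocyte course.
BOLD_SWITCH_GENES: frozenset[str] = frozenset({"Bhlhe40", "Hes1", "Id4"})
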