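"""Bundled study-condition presets for the synthetic clade generator.

The "fig4-like" preset emulates the published comparative setting: 17
Solanaceae-like leaves (two Convolvulaceae-like outgroups), a whole-genome
triplication shared by the entire clade, lineage-specific whole-genome
duplications on two producer terminal branches, a four-copy tandem cluster
of TRI on the Brugmansia-like branch, one translocated pathway gene (PPAR)
with eroded synteny in the Petunia-like clade, and three independent forced
losses of the HS-exclusive pathway segment (a Nicotiana/Petunia-like clade,
a Solanum/Capsicum-like clade, and the Lycium-like leaf).
"""

from __future__ import annotations

from .simulate import SimConfig, WgdSpec

# Ultrametric, branch lengths in My; internal nodes labelled so branches can
# be addressed by their child node label.
FIG4_TREE = (
    "((Inil:40,Itri:40)OUT:25,"
    "(((Pax:6,Pin:6)PET:14,Natt:20)NICPET:7,"
    "(((Barb:12,Dstr:12)DAT:9,"
    "((Stub:6,Slyc:6)SOL:6,(Smel:9,(Cann:5,Cbac:5)CAP:4)SOLB:3)SOLA:9)X1:2,"
    "(Lchi:17,((Atan:8,Hnig:8)HYO:6,(Mcau:10,Mand2:10)MAN:4)HYOMAN:3)LYC:6"
    ")X2:4)ING:38)ROOT;"
)

FIG4_PRODUCERS = ("Inil", "Itri", "Barb", "Dstr", "Atan", "Hnig",
                  "Mcau", "Mand2")
FIG4_LOSS_BRANCHES = ("NICPET", "SOLA", "Lchi")
FIG4_REFERENCES = ("Atan", "Barb", "Mcau")


def fig4_config(seed: int = 7) -> SimConfig:
    """The default fig4-like preset (3 pathway loss branches, WGT at root,
    WGD on the Anisodus- and Mandragora-like terminal branches, tandem TRI).

    Random loss/pseudogenization turnover applies to background genes only:
    the pathway truth in this preset is exactly the pattern imposed by the
    three forced loss events, which keeps the expected Dollo loss set
    well-defined while background events still exercise anchor filtering.
    """
    return SimConfig(
        seed=seed,
        n_chromosomes=2,
        n_background_genes_per_chrom=40,
        loss_rate=2e-4,
        pseudogenization_rate=2e-4,
        translocation_rate=0.0,
        wgd_branches={
            "Atan": WgdSpec(retention=0.5),
            "Mcau": WgdSpec(retention=0.5),
        },
        wgt_at_root=True,
        wgt_retention=0.25,
        tandem_dup_targets=[("Barb", "TRI", 3)],
        forced_translocations=[("PET", "PPAR")],
        pathway_loss_branches=list(FIG4_LOSS_BRANCHES),
        protect_pathway_background_events=True,
    )


def fig4_key_site_column() -> dict[str, str]:
    """A TRI-like conserved key-site column on the preset tree.

    Valine in 12 of 17 leaves, including every producer; the five
    Solanum/Capsicum-like non-producers drifted to Ala/Leu under relaxed
    constraint, mirroring the variable tropinone-binding sites.
    """
    column = {leaf: "V" for leaf in FIG4_PRODUCERS}
    column.update({"Lchi": "V", "Pax": "V", "Pin": "V", "Natt": "V"})
    column.update({"Stub": "A", "Slyc": "A", "Smel": "A",
                   "Cann": "L", "Cbac": "L"})
    return column
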