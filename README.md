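# petprofiler

Structural and biochemical analytics for PET-hydrolase characterization:
compare homologous enzyme backbones in Ramachandran space, superpose
structures rigidly, profile ensemble flexibility, and reduce the standard
PET-depolymerization assays to numbers.

## Who this is for

Groups characterizing polyethylene-terephthalate (PET) degrading enzymes —
PETases and cutinases, serine hydrolases that cleave PET ester bonds —
routinely ask the same quantitative questions: *where* do two homologous
structures genuinely differ, how flexible is each region, how stable is a
variant, and how much PET did a reaction actually depolymerize. This package
implements that analysis chain as a tested Python library with a thin CLI,
plus seeded synthetic-data generators so every stage can be validated without
downloading structures or instrument exports.

## What it computes

**Backbone-torsion divergence.** Cartesian superposition can hide local
main-chain differences, so homologs are compared per residue in Ramachandran
space. For aligned residues *i* with backbone dihedrals (φ, ψ):

    d_i = sqrt(Δφ_i² + Δψ_i²)   [degrees]

with angle differences wrapped to ±180° (the (φ, ψ) plane is a torus; a pair
straddling the seam is nearly identical, not ~360° apart). Region summaries
aggregate d_i over named residue ranges — e.g. the connecting loops that form
a PET hydrolase's active site — and the per-residue values can be written
into the B-factor column of a PDB file for putty-style rendering.

**Rigid superposition.** Kabsch (SVD) least-squares fitting of Cα atoms over
an alignment-derived correspondence, with iterative trimming of pairs beyond
`trim_factor × RMSD` so a few divergent loops do not dominate the reported
core RMSD.

**Ensemble fluctuations.** Per-residue Cα RMSF about the mean position of a
frame ensemble (multi-model PDB), optionally after Kabsch-fitting each frame
to a reference:

    RMSF_i = sqrt( mean_t |r_i(t) − ⟨r_i⟩|² )

**Sequence identity.** Needleman–Wunsch/Gotoh global alignment (BLOSUM62,
affine gaps 11/1, deterministic tie-breaking) and symmetric percent-identity
matrices over the aligned-column denominator.

**Assay reductions.**
- Melting temperature T_m as the first-derivative maximum of a thermal-shift
  melt curve (moving-average smoothing, parabolic sub-grid refinement).
- DSC crystallinity: (ΔH_m − ΔH_c)/ΔH_f × 100 with ΔH_f = 140.1 J/g for
  fully crystalline PET.
- HPLC quantification of TPA/MHET/BHET via per-analyte standard curves.
- Depolymerization extent: 100 × (mol TPA + mol MHET) × 192.17 / m_PET,
  one repeat unit (192.17 g/mol) released per aromatic product.
- pH-stat accounting: NaOH equivalents vs the 2:1:0 carboxyl stoichiometry
  of TPA:MHET:BHET.

## Worked example

Generate a 30-residue ideal helix and a "homolog" whose residues 10–14 carry
20° torsion perturbations — a synthetic divergent loop — then locate the
divergence:

```python
from petprofiler import (backbone_torsions, divergence_profile,
                         superpose_structures, AlignmentMap)
from petprofiler.synthetic_data import (GeneratorConfig, make_ideal_structure,
                                        perturb_torsions)

base = make_ideal_structure(30, "helix")
homolog = perturb_torsions(base, range(10, 15), sigma=20.0,
                           cfg=GeneratorConfig(seed=3))

sup = superpose_structures(base, homolog, trim_factor=2.0)
print(f"core RMSD {sup.rmsd:.2f} A over {sup.n_used}/{sup.n_initial} residues")

div = divergence_profile(backbone_torsions(base, "A"),
                         backbone_torsions(homolog, "A"),
                         AlignmentMap.identity(30))
print("top-5 divergent residues:",
      sorted(e.key[0] for e in div.top_k(5)))
```

prints

```
core RMSD 0.36 A over 21/30 residues
top-5 divergent residues: [10, 11, 12, 13, 14]
```

— a mid-chain torsion change swings the whole downstream arm in Cartesian
space, so trimming keeps only the self-consistent core (21 residues,
0.36 Å), while the Ramachandran profile pinpoints exactly the five perturbed
residues: the torsion-space signature stays local even when the Cartesian
picture does not.

The same flow from the shell:

```sh
petprofiler simulate structure --n 30 --out base.pdb
petprofiler simulate structure --n 30 --perturb 10-14 --sigma 20 --seed 3 --out homolog.pdb
petprofiler compare --ref base.pdb --other homolog.pdb --annotated-pdb putty.pdb
petprofiler assay crystallinity --dhm 50 --dhc 20          # -> 21.41 %
```

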