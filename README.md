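# ligpocket

Post-docking ligand–pocket interaction analysis: geometric hydrogen-bond
surveys (with and without binding-site waters), docking-pose clustering by
RMSD with lowest-energy coverage selection, activity/SAR table analytics,
and a synthetic complex generator so the whole pipeline is testable
offline.

## What it does

* **`ligpocket.structio`** — fixed-column PDB I/O (single complexes and
  multi-model pose ensembles with a sidecar energies TSV), atom-role
  partitioning (ligand / protein / water / ion), distance-rule covalent
  inference, and hydrogen-bond donor/acceptor typing.
* **`ligpocket.hbond`** — hydrogen-bond detection under a geometric
  criterion (H⋯acceptor distance strictly below 3.5 Å, donor–H⋯acceptor
  angle inclusively between 120° and 170°, both configurable), a focused
  analysis of a selected ligand atom (by default an acetyl carbonyl
  oxygen) against a named residue (Gln443 side-chain amide) and waters 1
  and 13, and per-ligand summaries (bonds/pose, mean H⋯A distance).
* **`ligpocket.clustering`** — no-superposition heavy-atom RMSD, greedy
  energy-seeded pose clustering within a 5 Å threshold, and selection of
  the lowest-energy clusters covering ≥70 % of poses.
* **`ligpocket.activity`** — typed activity table (IC50 in nM across
  enzyme/cellular assays plus an in-vivo tolerability column), pIC50,
  series extremes, potency screens, selectivity and dose-fold ratios,
  active/low-active class assignment, and Welch (or rank-sum) two-class
  comparisons.
* **`ligpocket.synth`** — deterministic toy binding pocket (glutamine
  probe residue 443, 14 waters, Zn/Mg ions, ligand with a uniquely named
  acetyl oxygen `OAC`), exact hydrogen-bond planting, pose ensembles with
  planted cluster structure, and two-class datasets whose drawn bond
  counts/distances are recovered verbatim by the detection pipeline.
* **`ligpocket.cli`** — `simulate`, `cluster`, `survey`, `compare`, `sar`
  and `run` subcommands writing reproducible TSV reports.

## CLI quick start

```sh
# generate a synthetic two-class dataset (8+8 ligands x 100 poses)
ligpocket simulate --out data/ --seed 0

# full pipeline: cluster -> survey -> summarize -> class comparison
ligpocket run --in data/ --out reports/ --mode both --seed 0

# single-ensemble operations
ligpocket cluster --pdb data/A1.pdb --energies data/A1_energies.tsv --out clusters.tsv
ligpocket survey  --pdb data/A1.pdb --mode with_water --out bonds.tsv

# activity-table analytics on the packaged table
ligpocket sar --out sar.tsv
```

Every report starts with a comment line naming the config hash and seed;
re-running an identical configuration reproduces byte-identical TSVs.

## Input conventions

* Structures: fixed-width PDB; waters named `HOH`/`SOL`/`WAT`; ions as
  single-atom residues; explicit hydrogens required (no protonation
  assignment is performed).
* Pose ensembles: `MODEL`/`ENDMDL` blocks with identical atom ordering
  plus a TSV with header `model<TAB>energy_kcal_mol`.
* Activity tables: TSV with header
  `compound_id series pde4b1_nM pde4a4_nM pde4d3_nM harbs_nM tnfa_hwb_nM
  tnfa_hpbmc_nM caco2_nM mned_mgkg`; missing cells are `nd`.
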