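# complexqa

Quality assessment for model biomolecular complexes. `complexqa` compares a
model structure against a reference and scores every inter-chain interface
with the standard docking measures:

- **fnat / fnonnat** — fraction of native residue contacts reproduced by the
  model (heavy atoms within 5 Å, 4 Å for peptides) and fraction of model
  contacts with no native counterpart;
- **iRMSD** — backbone RMSD of the reference-defined interface residues
  (heavy atoms within 10 Å; Cβ–Cβ within 8 Å for peptides);
- **LRMSD** — backbone RMSD of the smaller chain after superposing on the
  larger (receptor) chain;
- **DockQ** = (fnat + 1/(1+(iRMSD/1.5)²) + 1/(1+(LRMSD/8.5)²)) / 3, a
  continuous [0, 1] score with CAPRI class labels
  (Incorrect / Acceptable / Medium / High);
- **GlobalDockQ** — mean DockQ over all reference polymer interfaces;
- inter-chain **clash** counts (heavy-atom pairs closer than 2 Å).

Beyond protein–protein interfaces it handles:

- **nucleic-acid chains** (phosphate + primed sugar backbone for RMSDs);
- **small-molecule ligands** — scored by pocket-aligned all-heavy-atom LRMSD
  only. Ligand atoms are matched by element-labeled molecular-graph
  isomorphism (bonds perceived from covalent radii), and the reported LRMSD
  is minimized over all symmetry-equivalent atom mappings;
- **symmetric multimers** — the model↔reference chain mapping is found by
  exhaustive search over permutations within sequence-equivalence groups
  (k! candidates for a homo-k-mer), maximizing the global score, with
  memoized per-pair interface scores and optional multi-threading. Results
  are independent of thread count.

Inputs are PDB or mmCIF files, plain or gzip-compressed. Residues are paired
by global sequence alignment (default) or author numbering.

## Command line

```sh
complexqa MODEL REF [--mapping SPEC] [--no-align] [--n-workers N]
          [--json PATH] [--clash-cutoff Å] [--peptide-max-len N]
```

- `--mapping AB:BA` fixes the chain mapping (model chains A,B to reference
  chains B,A); `A*:A*` pins A→A and searches the rest; `:AB` restricts
  scoring to reference chains A and B.
- `--no-align` pairs residues by author numbering instead of alignment.
- `--json out.json` writes the full-precision machine-readable report next
  to the human-readable text on stdout.

Exit status is 0 on success, non-zero with a diagnostic on stderr otherwise.

## Library use

```python
import complexqa

model = complexqa.parse_structure("model.pdb")
ref = complexqa.parse_structure("ref.cif.gz")
result = complexqa.find_optimal_mapping(model, ref, n_workers=8)
print(result.global_dockq, result.mapping.as_dict())
```

Or run the whole pipeline exactly as the CLI does:

```python
from complexqa import RunConfig, run
report = run(RunConfig(model_path="model.pdb", ref_path="ref.pdb"))
print(report.to_json())
```

## Package layout

| module | contents |
| --- | --- |
| `io_structures` | PDB/mmCIF/gzip parsing, normalization, chain classification |
| `correspondence` | sequence alignment, residue pairing, chain-equivalence groups |
| `scoring` | contacts, fnat, Kabsch superposition, iRMSD/LRMSD, clashes, DockQ |
| `small_molecule` | bond perception, graph matching, pocket-aligned ligand LRMSD |
| `mapping_search` | mapping enumeration/counting, memoized exhaustive search |
| `cli` | argument parsing, report rendering (text + JSON) |
| `fixtures` | synthetic complex generator + minimal PDB/mmCIF writers (tests) |

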