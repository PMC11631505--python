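"""From trajectory to 3D-surface patches and their 18 descriptors.

Builds one synthetic antigen, constructs the 15 A patches around every
solvent-accessible residue (members weighted by the fraction of frames
they spend inside the patch) and prints the descriptor vector of one
patch: hydrophobicity, charge, dynamic accessibility and normalized
side-chain flexibility, each at central-residue and patch level.
"""

from epipatch import SynthConfig, generate_antigen_set
from epipatch.pipeline import process_antigen

bundle = generate_antigen_set(SynthConfig(n_antigens=1, n_loci=1, n_frames=20,
                                          seed=5))
result = process_antigen(bundle.ensembles[0])

patch = max(result.patches, key=lambda p: len(p.members))
c = patch.central
print(f"patch centered on chain {c.chain} position {c.position} ({c.aa}), "
      f"{len(patch.members)} members, radius {patch.radius} A")
print("members (chain:pos:aa -> frame-presence weight):")
for member, w in sorted(patch.members, key=lambda mw: -mw[1]):
    print(f"  {member.chain}:{member.position}:{member.aa}  w={w:.2f}")

print("\ndescriptors:")
for name, value in result.descriptors[c].as_dict().items():
    print(f"  {name:<14s} {value:8.3f}")
print("\nH_* are Kyte-Doolittle units; Pos/Neg count charged residues;"
      "\nS_* are RSASA percentages over the run; F_* are z-scored RMSF"
      "\n(negative = more rigid than the average accessible residue).")
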