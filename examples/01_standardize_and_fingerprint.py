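"""Standardize structures and compute the feature layer.

Salts are stripped, charges neutralized, stereo removed; every compound
becomes a canonical SMILES with a 1024-bit ECFP4 fingerprint and an
average molecular weight.
"""

from kinoscreen import (
    compute_ecfp4,
    molecular_weight,
    standardize_structure,
    tanimoto,
)

raw = {
    "ethanol-HCl salt": "CCO.Cl",
    "L-alanine (stereo)": "C[C@H](N)C(=O)O",
    "acetate anion": "CC(=O)[O-]",
    "naphthalene": "c1ccc2ccccc2c1",
}

print(f"{'input':22s} {'canonical':18s} {'MW (Da)':>8s} {'bits set':>9s}")
fps = {}
for name, smi in raw.items():
    canon = standardize_structure(smi)
    fp = compute_ecfp4(canon)
    fps[name] = fp
    print(f"{name:22s} {canon:18s} {molecular_weight(canon):8.2f} {int(fp.sum()):9d}")

sim = tanimoto(fps["ethanol-HCl salt"], fps["acetate anion"])
print(f"\nTanimoto(ethanol, acetic acid) = {sim:.3f}")
print("Similarity is intersection-over-union of the set fingerprint bits;")
print("small molecules share few circular substructures, so values are low.")
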