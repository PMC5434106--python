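"""Generate a synthetic 16S-like reference set with known truth.

Builds a five-genus set under the default study conditions (40 sequences per
genus, 1500 nt, 15% between- / 2% within-genus divergence, two engineered
primer-binding sites) and prints what the generator controls: the genus of
every sequence, the exact site coordinates, and the expected pairwise
identities implied by the substitution model.
"""

import dataclasses

import hcbprimer as h

cfg = h.SynthConfig(seed=1)
records, truth = h.generate_reference_set(cfg)

genera = sorted(set(truth.genus_of.values()))
print(f"generated {len(records)} sequences across {len(genera)} genera:")
for g in genera:
    n = sum(1 for v in truth.genus_of.values() if v == g)
    print(f"  {g}: {n} sequences, engineered pair coverage "
          f"{truth.expected_coverage(g):.2f}")

print("\nengineered primer sites (instantiated on the root):")
for motif, start in zip(truth.site_motifs, truth.site_starts):
    print(f"  {motif} at reference position {start}")

exp = h.expected_pairwise_identity(dataclasses.replace(cfg, indel_rate=0.0))
print(f"\nexpected pairwise identity (no indels): "
      f"within-genus {exp['within']:.4f}, between-genus {exp['between']:.4f}")
print("within >> between is what makes genus-level classification and "
      "monophyly recovery possible downstream.")
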