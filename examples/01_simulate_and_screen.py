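"""Simulate a planted protein database and screen it with a profile HMM.

Builds the default benchmark — five paralogous ~78-residue helical
domain families (one a truncated four-helix outgroup, one split into
two subfamilies) embedded in longer proteins with background flanks and
500 pure-background decoys — then estimates a profile HMM from the
cross-family seed alignment, calibrates its score statistics on decoys,
and screens the database at E < 1e-5.
"""

import numpy as np

from hhdscope import build_profile, calibrate, default_benchmark, search

bench = default_benchmark(seed=42)
print(f"database: {len(bench.database)} proteins, "
      f"{len(bench.truth.rows)} planted domain instances")

hmm = build_profile(bench.seed_msa)
median_len = int(np.median([len(s.residues) for s in bench.database]))
calibrate(hmm, n_decoys=5000, decoy_length=median_len, seed=42)
print(f"profile: {hmm.n_match_states} match states, "
      f"Gumbel mu={hmm.gumbel.mu:.2f} lambda={hmm.gumbel.lambda_gumbel:.3f}")

hits = search(hmm, bench.database, e_threshold=1e-5)
truth = {}
for r in bench.truth.rows:
    truth.setdefault(r.protein_id, []).append((r.dom_start, r.dom_end))
detected = sum(
    1 for pid, spans in truth.items() for s, e in spans
    if any(h.target_id == pid and min(e, h.end) - max(s, h.start) + 1
           >= 0.5 * (e - s + 1) for h in hits)
)
total = sum(len(v) for v in truth.values())
decoy_hits = sum(h.target_id.startswith("decoy") for h in hits)

print(f"hits at E<1e-5: {len(hits)}")
print(f"sensitivity: {detected}/{total} = {detected / total:.3f}")
print(f"hits on decoy proteins: {decoy_hits}")
print("-> nearly every planted domain is recovered and pure-background "
      "proteins stay below the significance threshold.")
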