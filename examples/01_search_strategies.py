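"""Seed-and-extend search with sensitivity-tuned strategies.

Plants one 35 %-diverged copy of a 90 nt query in a random background and
searches it with the blastn-default scoring and with strategy 7
(match +4 / mismatch -5, word size 7, relaxed E-cutoff).  At this
divergence the default word size (11) rarely seeds, while the tuned
strategy still finds the locus — the motivation for running an ensemble.
"""

import numpy as np

from ncranno.search import make_strategy, search, solve_statistics
from ncranno.seqio import Contig, QueryRecord
from ncranno.simulate import generate_background, mutate_to_identity

rng = np.random.default_rng(8)
query = generate_background(90, gc=0.5, seed=rng)
copy, realized = mutate_to_identity(query, 0.68, 0.01, seed=rng)
genome = [Contig("ctg1", generate_background(20_000, 0.36, rng)
                 + copy + generate_background(20_000, 0.36, rng))]
record = QueryRecord("famA", "snRNA", "CIN", query)
print(f"planted one copy at {realized:.2f} identity on ctg1:20000-{20000 + len(copy)}\n")

for sid in ("default", "7"):
    scheme = make_strategy(sid)
    stats = solve_statistics(scheme)
    hits = search(record, genome, scheme)
    print(f"strategy {sid:>7}  (r={scheme.r} q={scheme.q} W={scheme.W} "
          f"e_cut={scheme.e_cut:g}, lambda={stats.lambda_ka:.3f})")
    if not hits:
        print("   no hits\n")
        continue
    for h in sorted(hits, key=lambda h: -h.score)[:3]:
        print(f"   {h.interval.contig_id}:{h.interval.start}-{h.interval.end}"
              f"({h.interval.strand}) score={h.score} "
              f"identity={h.identity:.2f} E={h.evalue:.2g}")
    print()
print("The tuned strategy recovers the divergent copy; the default scoring")
print("is built for ~99 % identity targets and typically misses it.")
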