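"""Minimum-cost event paths between genome profiles.

Computes how many grammar events (fusion, fission, duplication, loss,
gain) separate two genome profiles, and prints the optimal path.
"""

from archevo import event_distance, parse_profile

pairs = [
    ("B-B-K-P", "B-B;K-P"),  # one fission by ORF separation
    ("B-K-P", "B;B-K-P"),    # tandem duplication, then separation
    ("B-B-K-P", "K-P"),      # one deletion spanning both folB copies
    (".", "K-P"),            # only a (costly) gene gain can create a profile
]

for src, dst in pairs:
    path = event_distance(parse_profile(src), parse_profile(dst))
    print(f"{src!r} -> {dst!r}: cost {path.total_cost}")
    for event in path.events:
        print(f"    {event.describe()}")

print(
    "\nEach line above is one grammar event; the cost is the number of"
    "\nevents, except gene gains which cost 10 (horizontal acquisition is"
    "\ndeliberately expensive, so vertical explanations win ties)."
)
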