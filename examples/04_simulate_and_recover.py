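"""Simulate architecture evolution, then try to recover it by parsimony.

Evolves a folB-folB-folK-folP root profile along a small tree under the
continuous-time event process, prints the simulated history, and runs the
simulate-then-infer recovery experiment showing that inferred parsimony
cost never exceeds the true number of simulated events.
"""

from archevo import parse_profile, read_newick, recovery_experiment, simulate

tree = read_newick("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")
root = parse_profile("B-B-K-P")

sim = simulate(tree, root, seed=7)
print("simulated tip profiles:")
for taxon, profile in sorted(sim.tip_profiles.items()):
    print(f"  {taxon}: {profile.text}")
print("true events:")
for branch, t, event in sim.true_events:
    print(f"  branch->node{branch} at t={t:.3f}: {event.describe()}")

df = recovery_experiment(tree, root, replicates=20, seed=7)
print("\nrecovery experiment (20 replicates):")
print(df[["true_events", "true_cost", "inferred_cost", "exact"]].to_string(index=False))
print(
    f"\nexact-recovery fraction: {df['exact'].mean():.2f}; the inferred cost "
    "is a lower bound on the true cost in every replicate (parsimony can "
    "only undercount when multiple events overwrite each other)."
)
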