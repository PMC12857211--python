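"""Recover open-pore surface densities from fresh synthetic tissues.

Each replicate generates a 60 µm tissue cube (110 cells, balanced cell
types), extracts interfaces, assigns the ground-truth pores by nearest
wall face, and estimates the OP density per interface class. The
generating intensities are TT 0.02, TP 0.01, PP 0.002 pores/µm².
"""

from pathlib import Path

from wallpore import studies
from wallpore.volume_io import write_table

N_SEEDS = 20
df = studies.recover_op_densities(N_SEEDS, base_seed=300)

out = Path("results/03_recovery")
out.mkdir(parents=True, exist_ok=True)
write_table(df, out / "op_densities.csv")

print(f"{N_SEEDS} tissues; mean estimated OP density (true in parentheses):")
for cls, lam in studies.OP_INTENSITY.items():
    est = df[f"density_{cls.lower()}"].mean()
    print(f"  {cls}: {est:.4f} /um2  (true {lam})")
print(f"rank order TT > TP > PP reproduced in {100*df['rank_correct'].mean():.0f}% of tissues")
tot = df[["total_density_tt", "total_density_tp", "total_density_pp"]].mean()
print(f"combined PD+OP density spread (max/min): {tot.max()/tot.min():.3f}")
print("per-seed table written to results/03_recovery/op_densities.csv")
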