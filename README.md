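# nterm

Quantitative analysis toolkit for probing the mobility of a membrane
transporter's N-terminus — the workflow built around LeuT, the bacterial
homolog of neurotransmitter:sodium symporters, whose N-terminal segment and
helix TM1A reposition between inward- and outward-facing states.

The package covers three measurement channels and the sequence bookkeeping
behind them:

* **LRET distances** (`nterm.lret`) — Tb³⁺ donor decays are fitted as sums of
  exponentials (instrument artifact + aggregation + reporter component), and
  reporter lifetimes without/with acceptor are inverted to a distance through
  the Förster relation `R = R₀·(τ_DA/(τ_D − τ_DA))^(1/6)`.
* **Iodide-quenching accessibility** (`nterm.quenching`) — emission titrations
  with KI are reduced to Stern–Volmer plots `F₀/F = 1 + K_SV·[Q]`; slopes and
  their standard errors decide whether labeling sites are equally
  water-exposed.
* **Conformational-ensemble observables** (`nterm.ensemble`) — multi-model PDB
  ensembles are reduced to Cα distance distributions against anchor residues
  (A335, H510), Kabsch superposition, and per-residue RMSF profiles.
* **Synthetic data with known ground truth** (`nterm.synthetic`) — Poisson
  photon-count decays, noisy quench titrations, and tethered freely-jointed
  chain ensembles in two regimes (free/disordered vs salt-bridge-locked, with
  optional membrane or micelle exclusion), used throughout the tests as
  recovery oracles.
* **Constructs** (`nterm.constructs`) — flank-checked insertion of the
  17-residue lanthanide binding tag (`YWDTNNDGWYEGDELLA`) between A335/G336,
  point mutants (K4C, H7C, A9C, R5A, R30A), FASTA I/O.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Estimate a donor–acceptor distance from replicate decay measurements with a
known ground truth of 5.5 nm (R₀ = 5.0 nm):

```python
from nterm.synthetic import DecayParams, simulate_decay
from nterm.lret import estimate_distance, tau_from_distance

R_true, R0, tau_D = 5.5, 5.0, 2.0
tau_DA = tau_from_distance(R_true, tau_D, R0)
donors = [simulate_decay(DecayParams(lifetimes=(0.05, 0.4, tau_D),
                                     amplitudes=(5000, 2000, 3000),
                                     noise="poisson", seed=s))
          for s in (1, 2, 3)]
das = [simulate_decay(DecayParams(lifetimes=(0.05, 0.4, tau_DA),
                                  amplitudes=(5000, 2000, 3000),
                                  noise="poisson", seed=s))
       for s in (4, 5, 6)]
est = estimate_distance(donors, das, R0=R0)
print(f"tau_D  = {est.tau_D:.4f} ms")
print(f"tau_DA = {est.tau_DA:.4f} ms")
print(f"R      = {est.R:.3f} +/- {est.sd:.3f} nm   (truth: {R_true} nm)")
```

prints

```
tau_D  = 1.9847 ms
tau_DA = 1.2464 ms
R      = 5.456 +/- 0.004 nm   (truth: 5.5 nm)
```

Each simulated trace is a Poisson-noised triple-exponential (~10⁴ peak
counts). The fit recovers the donor-only reporter lifetime τ_D ≈ 2 ms and the
quenched lifetime τ_DA, and the Förster inversion lands within 1 % of the true
distance; the ± value is the spread over the three replicates.

The same analyses are scriptable from the shell:

```sh
nterm constructs build --fasta wt.fa --insert LBT@335 --mutate K4C --out out.fa
nterm lret fit --trace trace.csv --n 3
nterm lret distance --donor d1.csv,d2.csv --da a1.csv,a2.csv --r0 5.0
nterm quench fit --spectra spectra_dir/ --wavelength 572
nterm ensemble distances --pdb ens.pdb --anchor 335 --targets 1-22
nterm ensemble rmsf --pdb ens.pdb --measure 5-22
nterm simulate decay|titration|ensemble --config cfg.json --seed 7 --out ...
```

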