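# Methods

## The model

A *megafund* invests `N·I` (millions) in `N` early-stage drug-development
programs and securitizes them through `M` special purpose vehicles (SPVs)
of `D` programs each, every program shared across `M·D/N` SPVs.  A
fraction `s` of capital funds one **senior tranche per SPV**, promised
`I_senior·(1+r)^T` at the horizon `T` (years) with
`I_senior = N·I·s/M`; the rest funds a **single pooled equity tranche**
(`I_equities = N·I·(1−s)`) that receives every SPV's residual, as if all
equity tranches were one.

A fraction `n/N` of the programs are *lemons*: programs with flaws known
to their promoters but not to investors.  In the closed-form layer a
lemon's success probability is exactly 0; each of the `N−n` non-lemons
succeeds independently with probability `p`, a success being worth `B`
(present value at `T`).

### Senior tranche

One success pays each holding SPV `B·N/(M·D)`.  The senior tranche is
whole when `k` successes cover the promise, i.e. when

    k ≥ K = ⌈ (D·I·s/B)·(1+r)^T ⌉,

so with `NL = D·(N−n)/N` non-lemons per SPV,

    d_senior = Σ_{k<K} C(NL,k) p^k (1−p)^{NL−k},
    V_senior = (1−d_senior)·I_senior·(1+r)^T + Σ_{k<K} P(k)·k·B·N/(M·D),
    y_senior = (V_senior/I_senior)^{1/T} − 1.

Both `K` and the ratio `V_senior/I_senior` are invariant in `M` (promise
and payments scale together), which the tests assert.

### Equity tranche

On average the fund produces `(N−n)·p` successes, so

    V_equities = (N−n)·p·B − M·V_senior,
    y_equity   = (V_equities/I_equities)^{1/T} − 1.

Equity defaults when the fund-wide success count `k` leaves less than
`I_equities` after the senior take.  Treating the senior take as fixed at
its promised level gives the threshold

    K′ = ⌈ (N·I·s·(1+r)^T + N·I·(1−s)) / B ⌉,
    d_equity = Σ_{k<K′} C(N−n,k) p^k (1−p)^{N−n−k}.

For a single SPV this is *exact* (the waterfall reduces to
`default ⇔ k·B < promise + I_equities`); for several SPVs it is an
estimate — the true senior take is random, and conditioning on a low `k`
lowers it — that errs on the prudent side.  Our Monte Carlo oracle for
the equity tail therefore samples the same fund-level construction
(aggregate promise fixed); a fully literal multi-SPV waterfall sits a few
points *below* the estimate, which is the approximation error, not a bug.

### Ideal and unfair funds

An *ideal* fund is the `n = 0` special case.  An *unfair* fund keeps all
lemons but splits its SPVs into `M1` clean ones (`d1` lemons each) and
`M2` toxic ones (`d2 > d1`), subject to lemon-slot conservation
`M1·d1 + M2·d2 = n·M·D/N`.  Each sub-fund is a reliable fund with
`NL_i = D − d_i`; overall default and value are the `M_i`-weighted
averages.  The unfair fund's pooled equity delegates to the reliable-fund
equity formulas on the base parameters.

## Reference values and known print discrepancies

The worked table bundled as `configs/table2.yaml` uses `N = 150`,
`I = 0.2`, `B = 12.3`, `s = 50 %`, `T = 10`.  Notes on the source table
this reproduces:

* Its preamble states `B = 13.6`, but every printed threshold, default
  probability and senior yield reproduces only with `B = 12.3` (the value
  given where the parameters are introduced).  `B` stays configurable;
  12.3 is the default.
* The printed **equity yields** (17.2 %, 24.0 %, 27.2 %, …) exceed the
  values the stated `V_equities` formula produces (14.6 %, 22.4 %,
  25.9 %, …) by 1.3–2.8 points in every case, and the printed **unfair
  senior yields** (5.9 %, 11.7 %) likewise do not follow from the stated
  weighted average (6.2 %, 12.6 %).  The package reports the formula
  values; the discrepancy is pinned by a dedicated test.
* The equity thresholds of the `r = 8.6 %` columns print as ⌈3.98⌉ = 4,
  but the `K′` formula at `r = 0.086` gives a pre-ceiling value of
  4.0024, hence `K′ = 5`; 3.98 follows only from `r = 0.085`.  The
  package keeps the formula-faithful result.
* One reliable-fund senior yield prints 8.3 % where the formulas give
  8.43 %, and the unfair `r = 16.8 %` senior default prints 41.8 % where
  the formulas give 41.86 % (rounding to 41.9); both are treated as print
  artifacts.  Table comparisons in the tests use a one-printed-ULP
  (0.1 point) tolerance for this reason.

## The simulator

The Monte Carlo engine replaces the one-shot binomial success model with
explicit dynamics: each program is a four-state chain
(Preclinical → Phase I → Sold / Failed) stepped per semester over a
12-semester (6-year) horizon; reaching Phase II sells the program
immediately at `sale_value`.  Lemons move under a derived matrix in which
advance probabilities are divided by a *severity* factor and failure
probabilities inflated by `1 + (severity−1)·(1+i)` for phase index `i` —
flawed programs that survive early screens fail harder later.

Default dynamics (calibration inputs, shipped in `configs/figure1.yaml`,
not facts from any source):

| quantity | default | rationale |
| --- | --- | --- |
| preclinical advance / fail (per semester) | 0.12 / 0.22 | non-lemon P(Sold by 12 sem) = 10.4 % |
| Phase I advance / fail | 0.10 / 0.22 | idem |
| lemon severity | 2.0 | lemon P(Sold) = 0.8 %, blended success ≈ 5.6 % |
| upfront / periodic / milestones | 0.1 / 0.005–0.01 / 0.02–0.05 | spend within the 0.2-per-program capital base |
| sale value | 12.3 | the closed-form `B` |
| cash rate | 1 % per semester | risk-free proxy on reserves |

A pool of 200 assets (half lemons) is screened by spending a fraction
`v` of total investment on validation; each lemon is detected
independently with probability `1 − e^{−10v}` (0 at `v = 0`, ~95 % at
`v = 0.3`), with no false positives by default.  The *ideal* fund drops
all lemons regardless of `v`; the *reliable* fund drops detected ones;
the *unfair* fund funds everything and packs detected lemons into
`⌊M/4⌋` toxic SPVs (toxic SPVs are filled with flagged assets first,
clean SPVs draw from the unflagged pool when it suffices).  `M = N/4`
SPVs of `D = N/2` assets are drawn randomly with the single constraint
that every asset joins at least one SPV (enforced by a swap-repair pass).
Validation also improves the characterization of non-lemons: their
advance probabilities scale by `1 + slope·v` (slope 1.0 by default; the
functional form is our choice, only the direction of the effect is
given).

Capital accounting: investors commit `C = N_funded·I/(1−v)`; `v·C` is
spent on validation and `N_funded·I` funds the programs, so tranche
principals — shares of the full `C` — make validation a real drag that
must pay for itself.  At the horizon each SPV's terminal value (cash plus
realized sales, interest-compounded, net of costs) is settled by the
waterfall.  Two settlement modes exist: **recovery** (default; a
defaulted senior receives whatever value its SPV has, matching the
closed-form default-branch payments) and **minimal** (a defaulted senior
receives nothing, the stricter stylization).  All residuals pool into
the single equity tranche either way, so payments exhaust terminal value
path by path — an invariant the tests assert.

The senior promise compounds over `promise_years` (default: the
simulated horizon in years; the analytic-reduction tests set it to the
closed-form `T = 10` explicitly).  RNG streams are spawned per path from
one master seed, so results are independent of execution order and
stable under extension of the path count.

### What the simulator does and does not show

The generator emulates: phase-structured attrition, information
asymmetry about program quality, validation screening with diminishing
returns, and the structural difference between spreading and
concentrating lemons.  It does not model correlated failures across
programs, post-Phase-II development, time-varying matrices, interim
coupons, junior tranches or coverage tests.  Passing sweep tests show
that the *directions* (validation reduces reliable-fund risk; toxic SPVs
become extremely risky as detection improves; ideal funds dominate) are
robust under these dynamics — not that real portfolios have these rates.

## Numerical choices

* Binomial tails use `scipy.stats.binom.cdf`/`pmf` (stable for `NL` up to
  10⁴ and beyond); nothing is computed via factorials.
* Ceilings at exact integers return that integer; a 1e−12 guard absorbs
  float noise in pre-ceiling values.
* A non-integral per-SPV non-lemon count `D·(N−n)/N` is an error in
  strict mode (the default; all worked cases are exactly divisible) and
  rounds to nearest with `strict=False`.
* A non-positive expected equity value reports value 0 with a
  `wiped_out` flag and a −100 %/yr yield rather than raising or returning
  a negative "value".
* A tranche paid nothing in the simulator likewise yields −100 %/yr.
* Degenerate structuring inputs (funded counts not divisible by 4) floor
  `M = N//4` with a warning.

## Problem sizes

Closed-form acceptance values are exact and instantaneous.  The test
suite runs its sampling checks at 10⁵ draws (single-period oracles),
8,000 paths (engine-vs-closed-form reduction) and 700 paths per
(behavior, v) cell for the qualitative sweep — sizes at which 3-standard-
error bands are decisive for the effects asserted; the bundled
`figure1.yaml` keeps the full 20,000-path configuration for study use.
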