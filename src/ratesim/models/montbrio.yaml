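# Exact mean-field model of all-to-all coupled quadratic integrate-and-fire
# neurons (Montbrio-type), in mean firing rate r and mean membrane potential
# V.  delta and eta are the spread and mean of the Lorentzian excitability
# distribution, J the intrinsic coupling, inp the input current; the time
# constant tau is 1 (time in units of tau, all variables unit-less).
#
# The default constants (delta = 1, eta = -5, J = 15) place the model in its
# bistable regime, where a stable node and a stable focus coexist and a
# transient input can switch between them.

MontbrioOperator:
  base: OperatorTemplate
  equations:
    - "d/dt * r = delta/(PI * tau**2) + 2.*r*V/tau"
    - "d/dt * V = (V**2 + eta + inp) / tau + J*r - tau*(PI*r)**2"
  variables:
    r:
      default: output
      description: mean firing rate
    V:
      default: variable
      description: mean membrane potential
    delta:
      default: 1.0
      description: spread of the excitability distribution
    eta:
      default: -5.0
      description: mean excitability
    J:
      default: 15.0
      description: intrinsic coupling strength
    tau:
      default: 1.0
      description: time constant (unit of time)
    inp:
      default: input
      description: extrinsic input current

MontbrioPopulation:
  base: NodeTemplate
  operators:
    - MontbrioOperator

MontbrioNetwork:
  base: CircuitTemplate
  nodes:
    Pop1: MontbrioPopulation
  edges: []
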