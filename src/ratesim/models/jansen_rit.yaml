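# Jansen-Rit cortical column: three coupled neural masses (pyramidal cells,
# excitatory and inhibitory interneurons).  Synaptic rate-to-potential
# operators are critically damped second-order kernels; the potential-to-rate
# operator is an instantaneous logistic function.
#
# Excitatory synapse constants follow the classic parametrization
# (h = 3.25 mV, tau = 10 ms); inhibitory and sigmoid constants adopt the
# standard literature values (|h_i| = 22 mV, tau_i = 20 ms, r_max = 5 /s,
# s = 560 /V, V_thr = 6 mV).  The inhibitory efficacy is stored with a
# negative sign because each population sums its synaptic PSP outputs into
# one membrane potential, so hyperpolarization must enter subtractively
# while all edge weights stay positive.

JansenRitSynapse:
  description: >
    Rate-to-potential operator: convolution of the incoming firing rate with
    a critically damped alpha kernel, written as two coupled first-order
    equations.
  base: OperatorTemplate
  equations:
    - "d/dt * V = V_t"
    - "d/dt * V_t = h/tau * r_in - (1./tau)^2 * V - 2.*1./tau*V_t"
  variables:
    r_in:
      default: input
      description: incoming presynaptic firing rate (1/s)
    V:
      default: output
      description: post-synaptic membrane potential contribution (V)
    V_t:
      default: variable
      description: integration variable
    tau:
      default: constant
      description: synaptic (lumped) time constant (s)
    h:
      default: constant
      description: synaptic efficacy (V); negative for inhibition

ExcitatorySynapse:
  base: JansenRitSynapse
  variables:
    h:
      default: 3.25e-3
    tau:
      default: 10e-3

InhibitorySynapse:
  base: JansenRitSynapse
  variables:
    h:
      default: -22e-3
    tau:
      default: 20e-3

JansenRitSynapse_with_input:
  description: >
    Excitatory synapse with an extrinsic drive u added to the presynaptic
    rate, for delivering external input to a population.
  base: ExcitatorySynapse
  equations:
    replace:
      r_in: (r_in + u)
  variables:
    u:
      default: input
      description: extrinsic input rate (1/s)

PotentialToRateOperator:
  description: >
    Instantaneous logistic potential-to-rate transform with maximum rate
    r_max, slope s and firing threshold V_thr.
  base: OperatorTemplate
  equations:
    - "r_out = r_max / (1. + exp(s*(V_thr - V)))"
  variables:
    V:
      default: input
      description: summed membrane potential (V)
    r_out:
      default: output
      description: outgoing population firing rate (1/s)
    r_max:
      default: 5.
    s:
      default: 560.
    V_thr:
      default: 6e-3

PyramidalCellPopulation:
  base: NodeTemplate
  operators:
    RPO_e: JansenRitSynapse_with_input
    RPO_i: InhibitorySynapse
    PRO: PotentialToRateOperator

ExcitatoryInterneurons:
  base: NodeTemplate
  operators:
    RPO_e: ExcitatorySynapse
    PRO: PotentialToRateOperator

InhibitoryInterneurons:
  base: NodeTemplate
  operators:
    RPO_e: ExcitatorySynapse
    PRO: PotentialToRateOperator

JansenRitCircuit:
  description: >
    Single cortical column at the standard connectivity scaling C = 135;
    edge weights are (0.25*C, C, 0.8*C, 0.25*C).
  base: CircuitTemplate
  nodes:
    EIN: ExcitatoryInterneurons
    IIN: InhibitoryInterneurons
    PC: PyramidalCellPopulation
  edges:
    - ["PC/PRO/r_out", "IIN/RPO_e/r_in", null, {weight: 33.75}]
    - ["PC/PRO/r_out", "EIN/RPO_e/r_in", null, {weight: 135.}]
    - ["EIN/PRO/r_out", "PC/RPO_e/r_in", null, {weight: 108.}]
    - ["IIN/PRO/r_out", "PC/RPO_i/r_in", null, {weight: 33.75}]

DoubleJRCircuit:
  description: >
    Two Jansen-Rit columns with bidirectional pyramidal-to-pyramidal
    coupling.
  base: CircuitTemplate
  circuits:
    JRC1: JansenRitCircuit
    JRC2: JansenRitCircuit
  edges:
    - ["JRC1/PC/PRO/r_out", "JRC2/PC/RPO_e/r_in", null, {weight: 10., delay: 0.0}]
    - ["JRC2/PC/PRO/r_out", "JRC1/PC/RPO_e/r_in", null, {weight: 10., delay: 0.0}]
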