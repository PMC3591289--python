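# Template for an eight-current leech-heart-interneuron-style cell.
#
# The kinetics of the published cell model are not bundled with this
# package; fill in the gating parameters (half-activations, slopes, time
# constants) and canonical maximal conductances from your source of choice.
# Values below are structural placeholders only: they define a valid,
# loadable model, not the published cell.  All analysis stages in the test
# suite run on the shipped surrogate models instead.
#
# Units: mV, nS, nF, nA, seconds.
model:
  name: leech_hn_template
  capacitance_nF: 0.5
  injected_current_nA: 0.0
  currents:
    - name: Na          # fast sodium
      reversal_mV: 45.0
      gbar_nS: 200.0
      activation: {name: m, exponent: 3,
                   steady_state: {v_half_mV: -29.0, k_mV: -5.0},
                   time_constant: {form: constant, base_s: 0.0001}}
      inactivation: {name: h, exponent: 1,
                     steady_state: {v_half_mV: -30.0, k_mV: 5.0},
                     time_constant: {form: bell, base_s: 0.004, amp_s: 0.006,
                                     v_half_mV: -29.0, k_mV: 15.0}}
    - name: P           # persistent sodium
      reversal_mV: 45.0
      gbar_nS: 7.0
      activation: {name: m, exponent: 1,
                   steady_state: {v_half_mV: -39.0, k_mV: -5.0},
                   time_constant: {form: bell, base_s: 0.01, amp_s: 0.2,
                                   v_half_mV: -39.0, k_mV: 10.0}}
    - name: CaF         # fast low-threshold calcium
      reversal_mV: 135.0
      gbar_nS: 5.0
      activation: {name: m, exponent: 2,
                   steady_state: {v_half_mV: -46.7, k_mV: -4.3},
                   time_constant: {form: constant, base_s: 0.011}}
      inactivation: {name: h, exponent: 1,
                     steady_state: {v_half_mV: -55.5, k_mV: 3.6},
                     time_constant: {form: bell, base_s: 0.06, amp_s: 0.31,
                                     v_half_mV: -55.0, k_mV: 10.0}}
    - name: CaS         # slow low-threshold calcium
      reversal_mV: 135.0
      gbar_nS: 3.2
      activation: {name: m, exponent: 2,
                   steady_state: {v_half_mV: -47.2, k_mV: -4.4},
                   time_constant: {form: bell, base_s: 0.005, amp_s: 0.134,
                                   v_half_mV: -48.0, k_mV: 12.0}}
      inactivation: {name: h, exponent: 1,
                     steady_state: {v_half_mV: -62.0, k_mV: 5.5},
                     time_constant: {form: bell, base_s: 0.2, amp_s: 5.25,
                                     v_half_mV: -61.0, k_mV: 12.0}}
    - name: h           # hyperpolarization-activated cation
      reversal_mV: -21.0
      gbar_nS: 4.0
      activation: {name: m, exponent: 2,
                   steady_state: {v_half_mV: -47.0, k_mV: 8.0},
                   time_constant: {form: sigmoid, base_s: 0.7, amp_s: 1.7,
                                   v_half_mV: -73.0, k_mV: -11.0}}
    - name: K1          # delayed rectifier
      reversal_mV: -70.0
      gbar_nS: 100.0
      activation: {name: m, exponent: 2,
                   steady_state: {v_half_mV: -21.0, k_mV: -8.0},
                   time_constant: {form: bell, base_s: 0.001, amp_s: 0.011,
                                   v_half_mV: -22.0, k_mV: 10.0}}
      inactivation: {name: h, exponent: 1,
                     steady_state: {v_half_mV: -28.0, k_mV: 4.0},
                     time_constant: {form: bell, base_s: 0.5, amp_s: 0.2,
                                     v_half_mV: -30.0, k_mV: 10.0}}
    - name: K2          # persistent potassium
      reversal_mV: -70.0
      gbar_nS: 80.0
      activation: {name: m, exponent: 2,
                   steady_state: {v_half_mV: -18.0, k_mV: -8.3},
                   time_constant: {form: bell, base_s: 0.057, amp_s: 0.043,
                                   v_half_mV: -20.0, k_mV: 15.0}}
    - name: KA          # fast transient potassium
      reversal_mV: -70.0
      gbar_nS: 80.0
      activation: {name: m, exponent: 2,
                   steady_state: {v_half_mV: -44.0, k_mV: -6.7},
                   time_constant: {form: bell, base_s: 0.005, amp_s: 0.011,
                                   v_half_mV: -30.0, k_mV: 15.0}}
      inactivation: {name: h, exponent: 1,
                     steady_state: {v_half_mV: -63.0, k_mV: 7.5},
                     time_constant: {form: bell, base_s: 0.026, amp_s: 0.0085,
                                     v_half_mV: -55.0, k_mV: 15.0}}
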