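{
  "version": "ciaaw-2021.1",
  "comment": "Isotope masses (Da) and fractional natural abundances for the elements relevant to carbohydrate/bisphosphonate host-guest chemistry. Masses from AME2020 via CIAAW; abundances are CIAAW representative values. Electron mass from CODATA 2018.",
  "electron_mass": 0.000548579909065,
  "elements": {
    "H": [[1.00782503207, 0.999885], [2.01410177812, 0.000115]],
    "C": [[12.0, 0.9893], [13.00335483507, 0.0107]],
    "N": [[14.00307400443, 0.99636], [15.00010889888, 0.00364]],
    "O": [[15.99491461957, 0.99757], [16.99913175650, 0.00038], [17.99915961286, 0.00205]],
    "Na": [[22.98976928, 1.0]],
    "P": [[30.97376199842, 1.0]]
  }
}
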