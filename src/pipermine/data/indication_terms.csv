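category,terms
Anxiety/Mood,"agitat*, anxiety, bipolar, depress*, despair, euphori*, fear, jitter, mood, nervousness, panic, phobia, restless, scared, stress, tension, uneasiness, worry"
Movement/Seizure,"chorea, clonus, convulsi*, dyskinesia, dystonia, epilep*, fits, jerk, rigidity, seizure, shaking, spasm, stiffness, trembl*, tremor"
Pain,"*ache, aching, agony, analgesi*, arthriti*, cramp, myalgia, narcotic, neuralgia, pain, rheumatism, soreness, throb"
Sleep,"calm, hypno*, insomnia, pacifier, relax*, sedati*, sleep, soporific, sudorific"
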