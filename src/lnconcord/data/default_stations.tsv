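code	band	anatomic_label	applicable_sites
201	locoregional	Pericolic, ileocolic	cecum;ascending
202	intermediate	Ileocolic artery	cecum
203	central	Ileocolic artery origin	cecum
211	locoregional	Pericolic, right colic	ascending;cecum
212	intermediate	Right colic artery	ascending
213	central	Right colic artery origin	ascending
214	central	Superior mesenteric artery nodes	ascending;transverse
221	locoregional	Pericolic, middle colic	transverse;ascending
222	intermediate	Middle colic artery	transverse
223	central	Middle colic artery origin	transverse
231	locoregional	Pericolic, left colic	descending;transverse;sigmoid
232	intermediate	Left colic artery	descending
233	central	Left colic artery origin	descending
241	locoregional	Pericolic, sigmoid	sigmoid;descending;superior_rectum
242	intermediate	Sigmoid arteries	sigmoid
251	locoregional	Pararectal, superior rectal	superior_rectum;middle_rectum;inferior_rectum;sigmoid
252	intermediate	Superior rectal artery	superior_rectum;middle_rectum;inferior_rectum
253	central	Inferior mesenteric artery origin	sigmoid;superior_rectum;middle_rectum;descending
261	locoregional	Perirectal, lateral	middle_rectum;inferior_rectum
262	intermediate	Internal iliac, proximal	inferior_rectum
263	intermediate	Internal iliac, distal	middle_rectum;inferior_rectum
272	central	Common iliac	middle_rectum;inferior_rectum
273	central	Obturator	inferior_rectum
283	central	Aortic bifurcation	inferior_rectum
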