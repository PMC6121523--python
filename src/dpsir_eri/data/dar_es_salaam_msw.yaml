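# Default DPSIR indicator hierarchy for municipal-solid-waste risk assessment
# (Dar es Salaam system: 5 indices, 18 indicators, 61 factors, 14 D- and 2
# E-subordinates). Leaves under the response index (A5) carry negative
# polarity: growth in those raw series lowers the risk score.
name: dar-es-salaam-msw
nodes:
  - {id: A1, label: Driving Forces}
  - {id: B1, label: Bio-physiological needs, parent: A1}
  - {id: C1, label: Food, parent: B1, polarity: positive}
  - {id: C2, label: Water, parent: B1, polarity: positive}
  - {id: C3, label: Shelter, parent: B1, polarity: positive}
  - {id: B2, label: Safety needs, parent: A1}
  - {id: C4, label: Healthcare, parent: B2, polarity: positive}
  - {id: C5, label: Protection from hostile environment, parent: B2, polarity: positive}
  - {id: B3, label: Belonging, parent: A1}
  - {id: C6, label: Need for family and community, parent: B3, polarity: positive}
  - {id: C7, label: Cultural practices, parent: B3, polarity: positive}
  - {id: A2, label: Pressure}
  - {id: B4, label: Population and society, parent: A2}
  - {id: C8, label: Population density, parent: B4, polarity: positive}
  - {id: C9, label: Population growth rate, parent: B4, polarity: positive}
  - {id: C10, label: Urbanization rate, parent: B4, polarity: positive}
  - {id: C11, label: Population below poverty line, parent: B4, polarity: positive}
  - {id: B5, label: Building and construction, parent: A2}
  - {id: C12, label: Number of new buildings, parent: B5, polarity: positive}
  - {id: C13, label: New built-up areas, parent: B5, polarity: positive}
  - {id: C14, label: Total covered land, parent: B5, polarity: positive}
  - {id: C15, label: Waste material generated, parent: B5, polarity: positive}
  - {id: B6, label: Institution and services, parent: A2}
  - {id: C16, label: Healthcare facilities (HCFs), parent: B6, polarity: positive}
  - {id: C17, label: Education services, parent: B6, polarity: positive}
  - {id: C18, label: Transport and communication, parent: B6, polarity: positive}
  - {id: C19, label: Other offices, parent: B6, polarity: positive}
  - {id: B7, label: Energy and material consumption, parent: A2}
  - {id: C20, label: Fuel, parent: B7, polarity: positive}
  - {id: C21, label: Material use (e.g. building), parent: B7, polarity: positive}
  - {id: B8, label: Economy, parent: A2}
  - {id: C22, label: GDP per-capita, parent: B8, polarity: positive}
  - {id: C23, label: Industries, parent: B8}
  - {id: D1, label: Services, parent: C23}
  - {id: E1, label: Hotels, parent: D1, polarity: positive}
  - {id: E2, label: Restaurants, parent: D1, polarity: positive}
  - {id: D2, label: Manufacturing, parent: C23, polarity: positive}
  - {id: C24, label: Agriculture, parent: B8, polarity: positive}
  - {id: C25, label: Markets (formal and informal), parent: B8, polarity: positive}
  - {id: A3, label: State}
  - {id: B9, label: MSW generation rate, parent: A3}
  - {id: C26, label: Domestic waste, parent: B9, polarity: positive}
  - {id: C27, label: Business and markets waste, parent: B9, polarity: positive}
  - {id: C28, label: Water bodies and fishing garbage, parent: B9, polarity: positive}
  - {id: C29, label: Waste from healthcare facilities, parent: B9, polarity: positive}
  - {id: C30, label: Construction and demolition, parent: B9, polarity: positive}
  - {id: C31, label: Industrial waste, parent: B9, polarity: positive}
  - {id: C32, label: Other major generators, parent: B9, polarity: positive}
  - {id: B10, label: MSW management status, parent: A3}
  - {id: C33, label: Total waste generated per year, parent: B10, polarity: positive}
  - {id: C34, label: Amount recycled, parent: B10, polarity: positive}
  - {id: C35, label: Total amount disposed, parent: B10, polarity: positive}
  - {id: C36, label: Amount left over, parent: B10, polarity: positive}
  - {id: C37, label: Annual tonnage of biohazard MSW (BhMSW), parent: B10, polarity: positive}
  - {id: B11, label: Pollution level, parent: A3}
  - {id: C38, label: Land pollution, parent: B11}
  - {id: D3, label: Settlement pattern, parent: C38, polarity: positive}
  - {id: C39, label: Water quality, parent: B11}
  - {id: D4, label: Toxicity level, parent: C39, polarity: positive}
  - {id: D5, label: Direction of underground water, parent: C39, polarity: positive}
  - {id: A4, label: Impacts}
  - {id: B12, label: Environment impacts, parent: A4}
  - {id: C40, label: Environmental hazards, parent: B12}
  - {id: D6, label: Persistent floods, parent: C40, polarity: positive}
  - {id: D7, label: Odor and aesthetics impacts, parent: C40, polarity: positive}
  - {id: C41, label: Ecosystem services (climate regulation, recreation), parent: B12, polarity: positive}
  - {id: B13, label: Social impacts (human health), parent: A4}
  - {id: C42, label: Malaria vector, parent: B13, polarity: positive}
  - {id: C43, label: Diarrhea, parent: B13, polarity: positive}
  - {id: C44, label: Cancer, parent: B13, polarity: positive}
  - {id: C45, label: Skin and respiratory diseases, parent: B13, polarity: positive}
  - {id: C46, label: Eye problems from uncontrolled burning, parent: B13, polarity: positive}
  - {id: C47, label: Injuries for scavengers and children, parent: B13, polarity: positive}
  - {id: C48, label: Deaths, parent: B13, polarity: positive}
  - {id: B14, label: Economic impacts, parent: A4}
  - {id: C49, label: Cost of abatement, parent: B14, polarity: positive}
  - {id: C50, label: Economic repercussions, parent: B14, polarity: positive}
  - {id: A5, label: Response}
  - {id: B15, label: Institutional framework, parent: A5}
  - {id: C51, label: Institutional capacities, parent: B15, polarity: negative}
  - {id: C52, label: Policies, law and regulations, parent: B15, polarity: negative}
  - {id: B16, label: Environmental education and publicity, parent: A5}
  - {id: C53, label: Promoting environmental management, parent: B16}
  - {id: D8, label: Raising public awareness, parent: C53, polarity: negative}
  - {id: D9, label: Stakeholders' involvement, parent: C53, polarity: negative}
  - {id: B17, label: Environmental governance and investment, parent: A5}
  - {id: C54, label: Funds for environmental projects, parent: B17, polarity: negative}
  - {id: C55, label: Enterprise environmental management, parent: B17, polarity: negative}
  - {id: C56, label: Other environmental management expenses, parent: B17, polarity: negative}
  - {id: B18, label: New approaches and modern technologies, parent: A5}
  - {id: C57, label: Landfill, parent: B18, polarity: negative}
  - {id: C58, label: Recycling, parent: B18, polarity: negative}
  - {id: C59, label: Incineration, parent: B18, polarity: negative}
  - {id: C60, label: Waste-to-energy technologies, parent: B18, polarity: negative}
  - {id: C61, label: Application of economic instruments (EIs), parent: B18}
  - {id: D10, label: Polluter pays principle (PPP), parent: C61, polarity: negative}
  - {id: D11, label: Landfill tax, parent: C61, polarity: negative}
  - {id: D12, label: Recycling credits, parent: C61, polarity: negative}
  - {id: D13, label: Fees and charges, parent: C61, polarity: negative}
  - {id: D14, label: DR-system and bond, parent: C61, polarity: negative}
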